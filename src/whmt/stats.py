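"""First-principles statistical machinery for the study-style tables.

Three procedures back every inferential table:

* Pearson product-moment correlation with a two-sided p from the
  t transform on n - 2 degrees of freedom;
* one-way ANOVA from between/within sums of squares;
* block-sequential ordinary least squares: main effects in block 1, all
  pairwise products of the *centered* block-1 predictors in block 2, with
  per-block R², the R² increment, adjusted R², standardized coefficients,
  and the overall F of the final model.

Everything is computed directly on numpy (scipy supplies only t and F
distribution tails).  Constant or collinear columns — e.g. the parental
dummy among participants who all have children — are dropped before
fitting and recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InputError


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value.

    Pairs with a missing value in either variable are dropped (listwise);
    at least 3 complete pairs are required; zero variance in either
    variable leaves the correlation undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("correlation undefined: zero variance")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p


def one_way_anova(groups) -> AnovaResult:
    """One-way ANOVA over a sequence of 1-D samples.

    F = MS_between / MS_within with df1 = k - 1, df2 = N - k.  All-identical
    data yields F = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    k = len(arrays)
    if k < 2 or any(a.size < 2 for a in arrays):
        raise DegenerateInputError("need >= 2 groups with >= 2 observations each")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df1, df2, p)


@dataclass
class RegressionSpec:
    """Outcome plus block-1 main effects; block 2 holds every pairwise
    product of the centered block-1 columns."""

    outcome: str
    block1: list[str]
    interactions: bool = True


@dataclass
class SequentialFit:
    """Block-sequential OLS summary in the layout of the study's tables."""

    outcome: str
    n: int
    r2_block1: float
    r2: float
    r2_change: float
    adj_r2: float
    beta_block1: dict[str, float]
    beta_block2: dict[str, float]
    F: float
    df1: int
    df2: int
    p: float
    dropped: list[str] = field(default_factory=list)


def _drop_degenerate(X: pd.DataFrame, tol: float = 1e-10) -> tuple[pd.DataFrame, list[str]]:
    """Remove constant columns, then columns that do not raise the rank."""
    dropped = [c for c in X.columns if np.std(X[c].to_numpy()) < tol]
    X = X.drop(columns=dropped)
    keep: list[str] = []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        mat = np.column_stack([np.ones(len(X)), trial])
        if np.linalg.matrix_rank(mat, tol=1e-8) == mat.shape[1]:
            keep.append(c)
        else:
            dropped.append(c)
    return X[keep], dropped


def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """R² and coefficients of an intercept-included least-squares fit."""
    mat = np.column_stack([np.ones(y.size), X]) if X.size else np.ones((y.size, 1))
    coef, *_ = np.linalg.lstsq(mat, y, rcond=None)
    resid = y - mat @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0.0:
        raise DegenerateInputError("outcome has zero variance")
    return float(1.0 - (resid @ resid) / ss_tot), coef


def sequential_ols(spec: RegressionSpec, data: pd.DataFrame) -> SequentialFit:
    """Fit the two-block sequential regression on a tidy DataFrame.

    Rows with any missing value among the outcome and block-1 predictors are
    dropped (listwise).  Standardized coefficients are raw coefficients
    rescaled by sd(x)/sd(y): block-1 betas from the main-effects model,
    interaction betas from the full model, matching how the tables report
    them.  Interaction columns are products of centered predictors, so each
    has mean ~0 by construction.
    """
    cols = [spec.outcome] + list(spec.block1)
    frame = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(frame)
    if n <= len(spec.block1) + 1:
        raise DegenerateInputError(
            f"{spec.outcome}: n={n} too small for {len(spec.block1)} predictors"
        )
    y = frame[spec.outcome].to_numpy(dtype=float)

    X1, dropped = _drop_degenerate(frame[list(spec.block1)].astype(float))
    if X1.shape[1] == 0:
        raise DegenerateInputError(f"{spec.outcome}: no usable predictors")

    inter = pd.DataFrame(index=frame.index)
    if spec.interactions:
        centered = X1 - X1.mean()
        for a, b in combinations(X1.columns, 2):
            inter[f"{a} x {b}"] = centered[a] * centered[b]
        inter, dropped2 = _drop_degenerate(pd.concat([X1, inter], axis=1))
        inter = inter.drop(columns=[c for c in X1.columns if c in inter.columns])
        dropped += [c for c in dropped2 if c not in X1.columns]

    r2_1, coef1 = _r2(y, X1.to_numpy())
    X_full = pd.concat([X1, inter], axis=1)
    r2_full, coef_full = _r2(y, X_full.to_numpy())

    sy = y.std(ddof=1)
    beta1 = {
        c: float(coef1[i + 1] * X1[c].std(ddof=1) / sy) for i, c in enumerate(X1.columns)
    }
    beta2 = {
        c: float(coef_full[1 + len(X1.columns) + i] * inter[c].std(ddof=1) / sy)
        for i, c in enumerate(inter.columns)
    }

    k = X_full.shape[1]
    df1, df2 = k, n - k - 1
    adj = 1.0 - (1.0 - r2_full) * (n - 1) / df2
    if r2_full >= 1.0:
        f, p = np.inf, 0.0
    else:
        f = (r2_full / df1) / ((1.0 - r2_full) / df2)
        p = float(sps.f.sf(f, df1, df2))
    return SequentialFit(
        outcome=spec.outcome,
        n=n,
        r2_block1=r2_1,
        r2=r2_full,
        r2_change=r2_full - r2_1,
        adj_r2=float(adj),
        beta_block1=beta1,
        beta_block2=beta2,
        F=float(f),
        df1=df1,
        df2=df2,
        p=p,
        dropped=dropped,
    )
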