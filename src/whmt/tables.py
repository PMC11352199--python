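"""Study-shaped descriptive and inferential tables from a scored DataFrame.

Each builder mirrors one table of the study's results section:

* ``demographics_table``       — age group x gender/romantic/parental counts;
* ``correlation_table``        — bivariate correlations among demographics
  and network-structure variables (per-role pairs use only participants who
  placed that role);
* ``composition_table``        — lives in :mod:`whmt.composition`;
* ``strength_regressions``     — sequential regressions of attachment
  strength per role on age + status dummies (+ centered interactions);
* ``proximity_table``          — per-role mile descriptives and distance-band
  counts/percentages;
* ``proximity_regressions``    — the same regressions on home distance;
* ``morphology_regressions``   — hierarchy (binary), attachment centrality,
  physical centrality and physical density as outcomes.

Degrees of freedom are always computed from the data actually used, never
copied from elsewhere.  p-values are reported unadjusted; pass
``fdr=True`` to append Benjamini-Hochberg adjusted q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagram import AGE_GROUP_LABELS, ROLE_ORDER
from .errors import DegenerateInputError
from .morphology import band_histogram
from .stats import RegressionSpec, SequentialFit, pearson_r, sequential_ols

#: Roles with a per-role column in the regression/proximity tables
#: ("other" is a catch-all and gets no role-specific model).
TABLE_ROLES = ("romantic_partner", "mother", "father", "sibling", "friend", "child")

#: Variables of the correlation table, in printed order.
CORRELATION_VARS = [
    ("age", "Age"),
    ("female", "Gender"),
    ("romantic", "Romantic Status"),
    ("parental", "Parental Status"),
    ("strength_romantic_partner", "Attachment Strength to Romantic Partner"),
    ("strength_mother", "Attachment Strength to Mother"),
    ("strength_father", "Attachment Strength to Father"),
    ("strength_friend", "Attachment Strength to Friend"),
    ("hierarchy", "Hierarchy vs. No Hierarchy"),
    ("physical_centrality", "Physical Centrality"),
    ("physical_density", "Physical Density"),
    ("attachment_centrality", "Attachment Strength Centrality"),
]


def demographics_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-age-group demographic counts and within-group percentages."""
    rows = []
    groups = [scored[scored["age_group"] == g] for g in AGE_GROUP_LABELS]
    for g, sub in zip(AGE_GROUP_LABELS, groups):
        rows.append(_demo_row(g, sub))
    rows.append(_demo_row("total", scored))
    return pd.DataFrame(rows)


def _demo_row(label: str, sub: pd.DataFrame) -> dict:
    n = len(sub)
    def pct(count):
        return 100.0 * count / n if n else 0.0
    male = int((sub["gender"] == "male").sum())
    female = int((sub["gender"] == "female").sum())
    single = int((sub["romantic_status"] == "single").sum())
    dating = int((sub["romantic_status"] == "dating").sum())
    married = int((sub["romantic_status"] == "married_engaged").sum())
    no_child = int((sub["parental_status"] == "no_child").sum())
    child = int((sub["parental_status"] == "child").sum())
    return {
        "age_group": label, "n": n,
        "male_n": male, "male_pct": pct(male),
        "female_n": female, "female_pct": pct(female),
        "single_n": single, "single_pct": pct(single),
        "dating_n": dating, "dating_pct": pct(dating),
        "married_engaged_n": married, "married_engaged_pct": pct(married),
        "no_child_n": no_child, "no_child_pct": pct(no_child),
        "child_n": child, "child_pct": pct(child),
    }


def correlation_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Lower-triangular matrix of pairwise Pearson correlations.

    Each pair is computed on the participants with both variables observed,
    so role-strength correlations automatically use the per-role subsample.
    Undefined correlations (a constant variable within the pair's
    subsample, e.g. romantic status among romantic-partner raters) are NaN.
    """
    cols = [c for c, _ in CORRELATION_VARS]
    mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    pvals = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        mat.loc[a, a] = 1.0
        for b in cols[:i]:
            try:
                r, p = pearson_r(scored[a], scored[b])
            except DegenerateInputError:
                continue
            mat.loc[a, b] = r
            pvals.loc[a, b] = p
    mat.attrs["p_values"] = pvals
    return mat


def _regressions(
    scored: pd.DataFrame, outcome_prefix: str, fdr: bool = False
) -> pd.DataFrame:
    fits: list[SequentialFit] = []
    for role in TABLE_ROLES:
        spec = RegressionSpec(
            outcome=f"{outcome_prefix}{role}",
            block1=["age", "parental", "romantic"],
        )
        try:
            fits.append(sequential_ols(spec, scored))
        except DegenerateInputError:
            continue
    return _fits_frame(fits, fdr)


def _fits_frame(fits: list[SequentialFit], fdr: bool = False) -> pd.DataFrame:
    rows = []
    for fit in fits:
        row = {
            "outcome": fit.outcome,
            "n": fit.n,
            "r2_block1": fit.r2_block1,
            "r2_change_block2": fit.r2_change,
            "r2": fit.r2,
            "adj_r2": fit.adj_r2,
            "F": fit.F,
            "df1": fit.df1,
            "df2": fit.df2,
            "p": fit.p,
            "dropped": "|".join(fit.dropped),
        }
        for name, beta in fit.beta_block1.items():
            row[f"beta_{name}"] = beta
        for name, beta in fit.beta_block2.items():
            row[f"beta_{name}"] = beta
        rows.append(row)
    frame = pd.DataFrame(rows)
    if fdr and len(frame):
        frame["q"] = benjamini_hochberg(frame["p"].to_numpy())
    return frame


def strength_regressions(scored: pd.DataFrame, fdr: bool = False) -> pd.DataFrame:
    """Sequential regressions of per-role attachment strength on
    age/parental/romantic (+ centered two-way interactions)."""
    return _regressions(scored, "strength_", fdr)


def proximity_regressions(scored: pd.DataFrame, fdr: bool = False) -> pd.DataFrame:
    """Sequential regressions of per-role home distance (miles)."""
    return _regressions(scored, "miles_", fdr)


def morphology_regressions(scored: pd.DataFrame, fdr: bool = False) -> pd.DataFrame:
    """Sequential regressions of the four morphology outcomes."""
    fits = []
    for outcome in (
        "hierarchy",
        "attachment_centrality",
        "physical_centrality",
        "physical_density",
    ):
        fits.append(
            sequential_ols(
                RegressionSpec(outcome=outcome, block1=["age", "parental", "romantic"]),
                scored,
            )
        )
    return _fits_frame(fits, fdr)


def proximity_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-role mile descriptives plus distance-band counts and percentages."""
    rows = []
    for role in TABLE_ROLES:
        d = scored[f"miles_{role}"].dropna()
        if d.empty:
            continue
        hist = band_histogram(d)
        row = {
            "role": role,
            "n": int(d.size),
            "mean_miles": float(d.mean()),
            "sd_miles": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        }
        for _, band in hist.iterrows():
            row[f"band_{band['band']}_n"] = int(band["count"])
            row[f"band_{band['band']}_pct"] = float(band["percent"])
        rows.append(row)
    return pd.DataFrame(rows)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (optional extra)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(ranked, 0, 1)
    return q
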