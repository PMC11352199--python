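"""Network-composition scoring: attachment strengths, clear-cut counting,
primary-figure identification, and per-age-group composition tabulation.

Attachment strength is the emotional diagram's radial pixel distance (0 =
strongest possible attachment).  A figure is a *clear-cut* attachment when
its strength is at or inside the inner-circle radius (60 px by default) —
the boundary counts as inside.  The *primary set* starts at the
minimum-strength figure and admits up to two more figures whose strength is
within the primary tolerance (15 px) of that minimum, capped at three.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diagram import (
    AGE_GROUP_LABELS,
    ROLE_ORDER,
    DiagramCalibration,
    ParticipantRecord,
    Thresholds,
    collapse_role,
    radial_distance,
)
from .errors import DegenerateInputError


@dataclass
class CompositionResult:
    """Per-participant composition scores."""

    strengths: dict[str, float]
    clear_cut_roles: list[str]
    n_clear_cut: int
    no_clear_cut_flag: bool
    primary_set: list[str]


def attachment_strengths(
    rec: ParticipantRecord, cal: DiagramCalibration
) -> dict[str, float]:
    """Radial pixel distance per placed role on the emotional diagram."""
    if not rec.emotional:
        raise DegenerateInputError(f"{rec.participant_id}: no emotional placements")
    return {p.role: radial_distance(p, cal) for p in rec.emotional}


def _role_rank(role: str) -> int:
    collapsed = collapse_role(role)
    try:
        return ROLE_ORDER.index(collapsed)
    except ValueError:
        return len(ROLE_ORDER)


def count_clear_cut(
    strengths: dict[str, float], th: Thresholds
) -> tuple[list[str], int, bool]:
    """Clear-cut roles (strength <= cut-off, boundary inside), their count,
    and a flag set when no figure qualifies."""
    if not strengths:
        raise DegenerateInputError("no strengths to classify")
    roles = sorted(
        (r for r, s in strengths.items() if s <= th.clear_cut_px),
        key=lambda r: (strengths[r], _role_rank(r), r),
    )
    return roles, len(roles), len(roles) == 0


def identify_primary(strengths: dict[str, float], th: Thresholds) -> list[str]:
    """Ordered primary set: the top-rated figure plus up to two figures
    within the primary tolerance of it, ascending by strength.

    Ties at identical strength are broken by the canonical role order, then
    alphabetically, so the result is deterministic.
    """
    if not strengths:
        raise DegenerateInputError("no strengths to rank")
    ordered = sorted(strengths, key=lambda r: (strengths[r], _role_rank(r), r))
    top = strengths[ordered[0]]
    primary = [r for r in ordered if strengths[r] - top <= th.primary_tol_px]
    return primary[:3]


def score_composition(
    rec: ParticipantRecord, cal: DiagramCalibration, th: Thresholds
) -> CompositionResult:
    strengths = attachment_strengths(rec, cal)
    clear_cut_roles, n_clear_cut, flag = count_clear_cut(strengths, th)
    return CompositionResult(
        strengths=strengths,
        clear_cut_roles=clear_cut_roles,
        n_clear_cut=n_clear_cut,
        no_clear_cut_flag=flag,
        primary_set=identify_primary(strengths, th),
    )


def composition_table(
    records: list[ParticipantRecord],
    cal: DiagramCalibration,
    th: Thresholds,
) -> pd.DataFrame:
    """Primary-figure nominations by age group and collapsed role category.

    ``percent`` is nominations / group n * 100; because a participant may
    have up to three primary figures, the per-group Total percent can
    exceed 100.  Empty groups yield zero rows with group n = 0.
    """
    counts = {g: {role: 0 for role in ROLE_ORDER} for g in AGE_GROUP_LABELS}
    group_n = {g: 0 for g in AGE_GROUP_LABELS}
    for rec in records:
        g = rec.age_group
        group_n[g] += 1
        primary = identify_primary(attachment_strengths(rec, cal), th)
        for role in primary:
            counts[g][collapse_role(role)] += 1

    rows = []
    for g in AGE_GROUP_LABELS:
        n = group_n[g]
        total = 0
        for role in ROLE_ORDER:
            c = counts[g][role]
            total += c
            rows.append(
                {
                    "age_group": g,
                    "group_n": n,
                    "role": role,
                    "count": c,
                    "percent": 100.0 * c / n if n else 0.0,
                }
            )
        rows.append(
            {
                "age_group": g,
                "group_n": n,
                "role": "total",
                "count": total,
                "percent": 100.0 * total / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
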