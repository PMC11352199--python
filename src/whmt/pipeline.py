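"""End-to-end scoring: participant records -> one tidy row of network metrics.

The scored DataFrame is the hand-off point between diagram scoring and the
statistical tables.  One row per participant with demographics, dummy codes
(romantic 0 = no partner / 1 = partner; parental 0 = no child / 1 = child),
composition scores, morphology scores, and per-role strength (px) and
home-distance (miles) columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .composition import score_composition
from .diagram import (
    ROLE_ORDER,
    DiagramCalibration,
    ParticipantRecord,
    Thresholds,
    collapse_role,
)
from .morphology import center_miles, score_morphology


def score_record(
    rec: ParticipantRecord,
    cal_emotional: DiagramCalibration,
    cal_physical: DiagramCalibration,
    th: Thresholds,
) -> dict:
    comp = score_composition(rec, cal_emotional, th)
    morph = score_morphology(rec, cal_emotional, cal_physical, th)
    miles = center_miles(rec, cal_physical)
    row = {
        "participant_id": rec.participant_id,
        "age": rec.age,
        "age_group": rec.age_group,
        "gender": rec.gender,
        "female": int(rec.gender == "female"),
        "romantic_status": rec.romantic_status,
        "parental_status": rec.parental_status,
        "romantic": int(rec.romantic_status != "single"),
        "parental": int(rec.parental_status == "child"),
        "n_roles": len(rec.emotional),
        "n_clear_cut": comp.n_clear_cut,
        "no_clear_cut": int(comp.no_clear_cut_flag),
        "primary_set": "|".join(comp.primary_set),
        "hierarchy_class": morph.hierarchy_class,
        "hierarchy": morph.hierarchy_binary,
        "attachment_centrality": morph.attachment_centrality,
        "physical_centrality": morph.physical_centrality,
        "physical_density": morph.physical_density,
    }
    strengths_by_cat: dict[str, float] = {}
    miles_by_cat: dict[str, float] = {}
    for role, s in comp.strengths.items():
        cat = collapse_role(role)
        # Keep the strongest figure when several collapse to one category.
        if cat not in strengths_by_cat or s < strengths_by_cat[cat]:
            strengths_by_cat[cat] = s
            miles_by_cat[cat] = miles[role]
    for cat in ROLE_ORDER:
        row[f"strength_{cat}"] = strengths_by_cat.get(cat, np.nan)
        row[f"miles_{cat}"] = miles_by_cat.get(cat, np.nan)
    return row


def score_records(
    records: list[ParticipantRecord],
    cal_emotional: DiagramCalibration | None = None,
    cal_physical: DiagramCalibration | None = None,
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Score every record with the given (or default) calibrations/thresholds."""
    cal_e = cal_emotional or DiagramCalibration.emotional_default()
    cal_p = cal_physical or DiagramCalibration.physical_default()
    thr = th or Thresholds()
    rows = [score_record(rec, cal_e, cal_p, thr) for rec in records]
    return pd.DataFrame(rows)
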