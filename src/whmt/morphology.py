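"""Whole-network shape metrics: hierarchy class, centrality, density, and
physical distance bands.

Hierarchy classification compares the gaps between the three strongest
attachment figures against one icon radius (18 px), the smallest visually
clear difference in closeness to centre.  With strengths sorted ascending
d1 <= d2 <= d3 <= ...:

* ``monotropic``     — d2 - d1 > gap: one clearly preferred figure;
* ``shared_primary`` — d2 - d1 <= gap and d3 - d2 > gap: two
  undifferentiated top figures above the rest;
* ``distributed``    — both gaps <= gap: top three undifferentiated.

The chained rule is exhaustive and mutually exclusive for any network of at
least three figures (the case where d3 - d1 > gap but both successive gaps
are small falls to ``distributed``).  The binary hierarchy code is 1 for
monotropic, 0 otherwise.

Centrality is the mean radial distance over all placed figures (attachment
strength in pixels on the emotional diagram, miles on the physical one);
density is the mean mile distance over every pair of figures.  Attachment
(emotional) density is deliberately not defined: respondents never place
figures relative to each other on the emotional diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diagram import (
    DiagramCalibration,
    ParticipantRecord,
    Thresholds,
    pairwise_mile_distances,
    pixels_to_miles,
    radial_distance,
)
from .errors import DegenerateInputError, InputError

HIERARCHY_CLASSES = ("monotropic", "shared_primary", "distributed")

#: Physical distance bands in miles: [0, 10], (10, 250], (250, 500], (500, inf).
BAND_LABELS = ("0-10", "11-250", "251-500", ">500")
BAND_EDGES = (10.0, 250.0, 500.0)


@dataclass
class MorphologyResult:
    """Per-participant morphology scores."""

    hierarchy_class: str
    hierarchy_binary: int
    attachment_centrality: float
    physical_centrality: float
    physical_density: float
    n_roles: int


def classify_hierarchy(strengths, th: Thresholds) -> str:
    """Hierarchy shape from attachment strengths (mapping or sequence).

    Requires at least three figures; the class is undefined below that.
    """
    if isinstance(strengths, Mapping):
        values = list(strengths.values())
    else:
        values = list(strengths)
    if len(values) < 3:
        raise DegenerateInputError(
            f"hierarchy class undefined for {len(values)} figure(s); need >= 3"
        )
    d = np.sort(np.asarray(values, dtype=float))
    gap = th.hierarchy_gap_px
    if d[1] - d[0] > gap:
        return "monotropic"
    if d[2] - d[1] > gap:
        return "shared_primary"
    return "distributed"


def hierarchy_binary(hierarchy_class: str) -> int:
    """Dichotomous hierarchy code: 1 = hierarchy (monotropic), 0 = no hierarchy."""
    if hierarchy_class not in HIERARCHY_CLASSES:
        raise InputError(f"unknown hierarchy class {hierarchy_class!r}")
    return int(hierarchy_class == "monotropic")


def attachment_centrality(strengths) -> float:
    """Mean attachment strength (pixels) over all placed figures."""
    values = list(strengths.values()) if isinstance(strengths, Mapping) else list(strengths)
    if not values:
        raise DegenerateInputError("no strengths to average")
    return float(np.mean(values))


def physical_centrality(rec: ParticipantRecord, cal: DiagramCalibration) -> float:
    """Mean mile distance from home to each placed figure."""
    if not rec.physical:
        raise DegenerateInputError(f"{rec.participant_id}: no physical placements")
    return float(np.mean(list(center_miles(rec, cal).values())))


def physical_density(rec: ParticipantRecord, cal: DiagramCalibration) -> float:
    """Mean mile distance over every pair of figures (lower = more clustered)."""
    _, mat = pairwise_mile_distances(rec, cal)
    iu = np.triu_indices(mat.shape[0], k=1)
    return float(np.mean(mat[iu]))


def center_miles(rec: ParticipantRecord, cal: DiagramCalibration) -> dict[str, float]:
    """Home-to-figure mile distance per placed role.

    Beyond-canvas radii are valid here (the top distance band extends past
    the outer ring through the calibration's extrapolation), so the
    outside-canvas warning is not re-raised per figure.
    """
    import warnings as _warnings

    from .diagram import OutsideCanvasWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", OutsideCanvasWarning)
        return {
            p.role: pixels_to_miles(radial_distance(p, cal), cal) for p in rec.physical
        }


def assign_band(miles: float) -> str:
    """Distance band for one mile value (bands right-closed at 10/250/500)."""
    if miles < 0:
        raise InputError(f"negative distance {miles}")
    for label, hi in zip(BAND_LABELS, BAND_EDGES):
        if miles <= hi:
            return label
    return BAND_LABELS[-1]


def band_histogram(distances: Iterable[float]) -> pd.DataFrame:
    """Counts and percentages of mile distances per band.

    Percentages sum to 100 (up to rounding) whenever any distance is given.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size and np.any(d < 0):
        raise InputError("distances must be non-negative")
    edges = np.array([0.0, *BAND_EDGES, np.inf])
    counts, _ = np.histogram(d, bins=edges)
    # np.histogram bins are left-closed; shift boundary values to honour
    # right-closed bands [0,10], (10,250], (250,500].
    for i, hi in enumerate(BAND_EDGES):
        on_edge = int(np.count_nonzero(d == hi))
        if on_edge and i + 1 < len(counts):
            counts[i] += on_edge
            counts[i + 1] -= on_edge
    n = counts.sum()
    return pd.DataFrame(
        {
            "band": BAND_LABELS,
            "count": counts,
            "percent": 100.0 * counts / n if n else np.zeros(len(BAND_LABELS)),
        }
    )


def score_morphology(
    rec: ParticipantRecord,
    cal_emotional: DiagramCalibration,
    cal_physical: DiagramCalibration,
    th: Thresholds,
) -> MorphologyResult:
    strengths = {p.role: radial_distance(p, cal_emotional) for p in rec.emotional}
    cls = classify_hierarchy(strengths, th)
    return MorphologyResult(
        hierarchy_class=cls,
        hierarchy_binary=hierarchy_binary(cls),
        attachment_centrality=attachment_centrality(strengths),
        physical_centrality=physical_centrality(rec, cal_physical),
        physical_density=physical_density(rec, cal_physical),
        n_roles=len(strengths),
    )
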