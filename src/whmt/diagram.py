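"""Domain types and radial geometry for concentric-circle network diagrams.

The hierarchical mapping technique asks a respondent to place up to five
self-selected relationship figures on two calibrated concentric-circle
canvases.  On the *emotional* diagram the radial pixel distance from the
centre ("you") encodes attachment strength — lower is stronger, 0 at the
centre, up to 700 outside the third ring.  On the *physical* diagram the
centre is the respondent's home and the three rings are mile anchors
(10, 250 and 500 miles by default); radial pixel distance maps to
geographic distance through a piecewise-linear calibration exact at each
ring.

Screen convention: the canvas y axis increases downward, so north is -y.
``to_mile_plane`` flips the axis so that in mile coordinates up is north
and right is east.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, DegenerateInputError, InputError, ValidationError

EMOTIONAL = "emotional"
PHYSICAL = "physical"
DIAGRAM_KINDS = (EMOTIONAL, PHYSICAL)

#: Canonical collapsed role categories, in the fixed order used to break
#: ties between figures placed at identical radii.
ROLE_ORDER = (
    "romantic_partner",
    "mother",
    "father",
    "sibling",
    "friend",
    "child",
    "other",
)

#: Aliases mapping the instrument's 17-role dropdown (plus common write-ins)
#: onto the collapsed categories.  "child" only ever arrives as a write-in.
ROLE_ALIASES = {
    "romantic partner": "romantic_partner",
    "partner": "romantic_partner",
    "spouse": "romantic_partner",
    "husband": "romantic_partner",
    "wife": "romantic_partner",
    "boyfriend": "romantic_partner",
    "girlfriend": "romantic_partner",
    "fiance": "romantic_partner",
    "fiancee": "romantic_partner",
    "mom": "mother",
    "stepmother": "mother",
    "dad": "father",
    "stepfather": "father",
    "sister": "sibling",
    "brother": "sibling",
    "best friend": "friend",
    "close friend": "friend",
    "son": "child",
    "daughter": "child",
    "grandmother": "other",
    "grandfather": "other",
    "aunt": "other",
    "uncle": "other",
    "cousin": "other",
    "coworker": "other",
    "neighbor": "other",
}


def collapse_role(role: str, aliases: dict[str, str] | None = None) -> str:
    """Normalise a raw role label to one of the seven collapsed categories."""
    key = role.strip().lower().replace("-", " ").replace("_", " ")
    key_canon = key.replace(" ", "_")
    if key_canon in ROLE_ORDER:
        return key_canon
    table = ROLE_ALIASES if aliases is None else {**ROLE_ALIASES, **aliases}
    return table.get(key, "other")


class OutsideCanvasWarning(UserWarning):
    """A placement lies beyond the calibrated maximum radius (kept, not clipped)."""


@dataclass(frozen=True)
class Placement:
    """One relationship figure at an (x, y) pixel position on one diagram."""

    role: str
    x: float
    y: float
    diagram: str

    def __post_init__(self):
        if not self.role or not str(self.role).strip():
            raise ValidationError("placement role must be non-empty")
        if self.diagram not in DIAGRAM_KINDS:
            raise ValidationError(f"unknown diagram kind {self.diagram!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"non-finite coordinates for role {self.role!r}")


@dataclass(frozen=True)
class DiagramCalibration:
    """Canvas centre, ring radii and (for the physical diagram) mile anchors.

    The printed score range is 0 at the centre to ``max_radius`` (700)
    outside the third ring.  Ring radii must satisfy 0 < R1 < R2 < R3 <=
    max_radius.  Emotional calibrations carry no mile anchors.
    """

    kind: str
    center_x: float = 0.0
    center_y: float = 0.0
    ring_radii: tuple[float, float, float] = (60.0, 380.0, 700.0)
    max_radius: float = 700.0
    ring_miles: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.kind not in DIAGRAM_KINDS:
            raise CalibrationError(f"unknown diagram kind {self.kind!r}")
        r1, r2, r3 = self.ring_radii
        if not (0 < r1 < r2 < r3 <= self.max_radius):
            raise CalibrationError(
                f"ring radii must satisfy 0 < R1 < R2 < R3 <= max_radius, got {self.ring_radii}"
            )
        if self.kind == EMOTIONAL and self.ring_miles is not None:
            raise CalibrationError("emotional calibration carries no mile anchors")
        if self.kind == PHYSICAL:
            if self.ring_miles is None:
                raise CalibrationError("physical calibration requires mile anchors")
            m1, m2, m3 = self.ring_miles
            if not (0 < m1 < m2 < m3):
                raise CalibrationError("mile anchors must be strictly increasing")

    @classmethod
    def emotional_default(cls) -> "DiagramCalibration":
        # Inner ring identified with the 60 px clear-cut radius.
        return cls(kind=EMOTIONAL, ring_radii=(60.0, 380.0, 700.0))

    @classmethod
    def physical_default(cls) -> "DiagramCalibration":
        # Ring pixel radii are not part of the instrument's printed output;
        # equal spacing over the 700 px canvas is the default.
        return cls(
            kind=PHYSICAL,
            ring_radii=(233.0, 466.0, 700.0),
            ring_miles=(10.0, 250.0, 500.0),
        )


@dataclass(frozen=True)
class Thresholds:
    """The three classification cut-offs, in pixels.

    clear_cut_px: inner-circle radius; figures at or inside it are clear-cut
    attachment figures.  primary_tol_px: figures within this distance of the
    top-rated figure share primacy (up to three).  hierarchy_gap_px: one icon
    radius — the smallest visually clear difference in closeness, used to
    classify hierarchy shape.
    """

    clear_cut_px: float = 60.0
    primary_tol_px: float = 15.0
    hierarchy_gap_px: float = 18.0

    def __post_init__(self):
        if min(self.clear_cut_px, self.primary_tol_px, self.hierarchy_gap_px) <= 0:
            raise ValidationError("all thresholds must be strictly positive")


#: Age bins partitioning [24, inf): (label, lo, hi) with hi the last whole
#: year in the bin (24-34, 35-44, 45-64, 65+).
AGE_BINS = (
    ("early_adulthood", 24, 34),
    ("early_middle", 35, 44),
    ("late_middle", 45, 64),
    ("late_adulthood", 65, math.inf),
)

AGE_GROUP_LABELS = tuple(b[0] for b in AGE_BINS)


def age_group(age: float) -> str:
    """Map an age in years to its study age group label.

    Bins are half-open on the real line ([24, 35), [35, 45), [45, 65),
    [65, inf)) so fractional ages map to the bin of their whole year.
    """
    if age < AGE_BINS[0][1]:
        raise InputError(f"age {age} below study inclusion minimum of {AGE_BINS[0][1]}")
    for (label, lo, _), nxt in zip(AGE_BINS, AGE_BINS[1:] + (None,)):
        if nxt is None or age < nxt[1]:
            return label
    raise AssertionError("unreachable: bins partition [24, inf)")


GENDERS = ("male", "female")
ROMANTIC_STATUSES = ("single", "dating", "married_engaged")
PARENTAL_STATUSES = ("no_child", "child")


@dataclass
class ParticipantRecord:
    """Demographics plus both diagrams for one respondent.

    The emotional and physical diagrams must cover the same 1-5 roles, one
    placement per role per diagram.  Ages below 24 violate the study's
    inclusion criterion unless ``allow_underage`` is set.
    """

    participant_id: str
    age: float
    gender: str
    romantic_status: str
    parental_status: str
    emotional: list[Placement] = field(default_factory=list)
    physical: list[Placement] = field(default_factory=list)
    allow_underage: bool = False

    def __post_init__(self):
        problems = []
        if self.age < 24 and not self.allow_underage:
            problems.append(f"{self.participant_id}: age {self.age} below inclusion minimum 24")
        if self.gender not in GENDERS:
            problems.append(f"{self.participant_id}: unknown gender {self.gender!r}")
        if self.romantic_status not in ROMANTIC_STATUSES:
            problems.append(f"{self.participant_id}: unknown romantic status {self.romantic_status!r}")
        if self.parental_status not in PARENTAL_STATUSES:
            problems.append(f"{self.participant_id}: unknown parental status {self.parental_status!r}")
        for name, placements, kind in (
            ("emotional", self.emotional, EMOTIONAL),
            ("physical", self.physical, PHYSICAL),
        ):
            roles = [p.role for p in placements]
            if len(set(roles)) != len(roles):
                problems.append(f"{self.participant_id}: duplicate role on {name} diagram")
            if any(p.diagram != kind for p in placements):
                problems.append(f"{self.participant_id}: {name} list contains wrong-diagram placement")
        e_roles = {p.role for p in self.emotional}
        p_roles = {p.role for p in self.physical}
        if e_roles != p_roles:
            problems.append(f"{self.participant_id}: emotional and physical role sets differ")
        if not 1 <= len(e_roles) <= 5:
            problems.append(f"{self.participant_id}: expected 1-5 roles, got {len(e_roles)}")
        if problems:
            raise ValidationError(problems)

    @property
    def roles(self) -> list[str]:
        return [p.role for p in self.emotional]

    @property
    def age_group(self) -> str:
        return age_group(self.age)


# ---------------------------------------------------------------------------
# Radial geometry


def radial_distance(p: Placement, cal: DiagramCalibration) -> float:
    """Euclidean pixel distance from the calibration centre to a placement.

    Placements beyond ``max_radius`` are legitimate scores ("outside the
    third circle"): the distance is returned unchanged and an
    :class:`OutsideCanvasWarning` is emitted.
    """
    if p.diagram != cal.kind:
        raise CalibrationError(
            f"placement on {p.diagram!r} diagram scored with {cal.kind!r} calibration"
        )
    r = math.hypot(p.x - cal.center_x, p.y - cal.center_y)
    if r > cal.max_radius:
        warnings.warn(
            f"placement for {p.role!r} at {r:.1f} px exceeds max radius {cal.max_radius}",
            OutsideCanvasWarning,
            stacklevel=2,
        )
    return r


def beyond_canvas(p: Placement, cal: DiagramCalibration) -> bool:
    """True when a placement lies beyond the calibrated maximum radius."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OutsideCanvasWarning)
        return radial_distance(p, cal) > cal.max_radius


def _require_physical(cal: DiagramCalibration):
    if cal.kind != PHYSICAL or cal.ring_miles is None:
        raise CalibrationError("mile conversion requires a physical calibration")


def pixels_to_miles(r, cal: DiagramCalibration):
    """Piecewise-linear pixel-to-mile map through the ring anchors.

    Exact at 0 -> 0 and at each ring (R1 -> 10, R2 -> 250, R3 -> 500 by
    default); linear extrapolation beyond R3 at the last segment's slope.
    Accepts scalars or arrays.
    """
    _require_physical(cal)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InputError("radial distance must be non-negative")
    xp = np.array([0.0, *cal.ring_radii])
    fp = np.array([0.0, *cal.ring_miles])
    slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    miles = np.where(r <= xp[-1], np.interp(r, xp, fp), fp[-1] + (r - xp[-1]) * slope)
    return float(miles) if miles.ndim == 0 else miles


def miles_to_pixels(m, cal: DiagramCalibration):
    """Inverse of :func:`pixels_to_miles` (exact on the anchors, extrapolating above)."""
    _require_physical(cal)
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise InputError("mile distance must be non-negative")
    xp = np.array([0.0, *cal.ring_miles])
    fp = np.array([0.0, *cal.ring_radii])
    slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    px = np.where(m <= xp[-1], np.interp(m, xp, fp), fp[-1] + (m - xp[-1]) * slope)
    return float(px) if px.ndim == 0 else px


def to_mile_plane(p: Placement, cal: DiagramCalibration) -> tuple[float, float]:
    """Map a physical placement to mile coordinates, preserving its bearing.

    The radial coordinate is the mile-converted radial distance; the angle
    from the centre is kept.  Output convention: +y is north, +x is east
    (the screen y axis, which grows downward, is flipped).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OutsideCanvasWarning)
        r_px = radial_distance(p, cal)
    _require_physical(cal)
    if r_px == 0.0:
        return (0.0, 0.0)
    r_mi = pixels_to_miles(r_px, cal)
    ux = (p.x - cal.center_x) / r_px
    uy = -(p.y - cal.center_y) / r_px  # flip screen y so north is +y
    return (r_mi * ux, r_mi * uy)


def pairwise_mile_distances(
    rec: ParticipantRecord, cal: DiagramCalibration
) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of mile distances between every pair of figures.

    Distances are Euclidean in the mile plane (angles preserved, radii
    mapped through the calibration), so centre distances and between-figure
    distances live on the same scale.  Requires >= 2 physical placements.
    """
    if len(rec.physical) < 2:
        raise DegenerateInputError(
            f"{rec.participant_id}: need >= 2 physical placements for pairwise distances"
        )
    roles = [p.role for p in rec.physical]
    pts = np.array([to_mile_plane(p, cal) for p in rec.physical])
    diff = pts[:, None, :] - pts[None, :, :]
    return roles, np.hypot(diff[..., 0], diff[..., 1])
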