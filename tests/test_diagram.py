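"""Radial geometry, calibration, and the pixel-to-mile map."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whmt import (
    CalibrationError,
    DiagramCalibration,
    InputError,
    OutsideCanvasWarning,
    Placement,
    ValidationError,
    age_group,
    collapse_role,
    miles_to_pixels,
    pairwise_mile_distances,
    pixels_to_miles,
    radial_distance,
    to_mile_plane,
)
from whmt.diagram import beyond_canvas

from conftest import make_record


class TestRadialDistance:
    def test_center_is_zero(self, cal_emot):
        assert radial_distance(Placement("mother", 0, 0, "emotional"), cal_emot) == 0.0

    def test_pythagorean_triple(self, cal_emot):
        p = Placement("friend", 300, 400, "emotional")
        assert radial_distance(p, cal_emot) == pytest.approx(500.0)

    def test_in_canvas_range(self, cal_emot):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r, a = rng.uniform(0, 700), rng.uniform(0, 2 * math.pi)
            p = Placement("friend", r * math.cos(a), r * math.sin(a), "emotional")
            assert 0.0 <= radial_distance(p, cal_emot) <= 700.0

    def test_rotation_invariant(self, cal_emot):
        rng = np.random.default_rng(1)
        r0 = rng.uniform(0, 650)
        dists = set()
        for a in rng.uniform(0, 2 * math.pi, size=10):
            p = Placement("x", r0 * math.cos(a), r0 * math.sin(a), "emotional")
            dists.add(round(radial_distance(p, cal_emot), 9))
        assert len(dists) == 1

    def test_kind_mismatch_raises(self, cal_emot):
        with pytest.raises(CalibrationError):
            radial_distance(Placement("m", 1, 1, "physical"), cal_emot)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(InputError):
            Placement("m", float("nan"), 0, "emotional")

    def test_beyond_canvas_flagged_not_clipped(self, cal_emot):
        p = Placement("m", 800, 0, "emotional")
        with pytest.warns(OutsideCanvasWarning):
            assert radial_distance(p, cal_emot) == pytest.approx(800.0)
        assert beyond_canvas(p, cal_emot)


class TestMileConversion:
    def test_anchors_exact(self, cal_phys):
        r1, r2, r3 = cal_phys.ring_radii
        assert pixels_to_miles(0.0, cal_phys) == 0.0
        assert pixels_to_miles(r1, cal_phys) == pytest.approx(10.0)
        assert pixels_to_miles(r2, cal_phys) == pytest.approx(250.0)
        assert pixels_to_miles(r3, cal_phys) == pytest.approx(500.0)

    def test_linear_midpoint(self, cal_phys):
        r1, r2, _ = cal_phys.ring_radii
        assert pixels_to_miles((r1 + r2) / 2, cal_phys) == pytest.approx(130.0)

    @given(st.floats(min_value=0.0, max_value=700.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_on_canvas(self, r):
        cal = DiagramCalibration.physical_default()
        assert miles_to_pixels(pixels_to_miles(r, cal), cal) == pytest.approx(
            r, rel=1e-9, abs=1e-9
        )

    @given(st.floats(min_value=0.0, max_value=699.0), st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, r, dr):
        cal = DiagramCalibration.physical_default()
        assert pixels_to_miles(r + dr, cal) >= pixels_to_miles(r, cal)

    def test_extrapolates_beyond_outer_ring(self, cal_phys):
        r2, r3 = cal_phys.ring_radii[1], cal_phys.ring_radii[2]
        slope = 250.0 / (r3 - r2)
        assert pixels_to_miles(r3 + 100, cal_phys) == pytest.approx(500 + 100 * slope)

    def test_emotional_calibration_rejected(self, cal_emot):
        with pytest.raises(CalibrationError):
            pixels_to_miles(100.0, cal_emot)


class TestMilePlane:
    def test_center_maps_to_origin(self, cal_phys):
        assert to_mile_plane(Placement("m", 0, 0, "physical"), cal_phys) == (0.0, 0.0)

    def test_due_north_at_first_ring(self, cal_phys):
        # Screen y grows downward, so north is -y in pixels and +y in miles.
        r1 = cal_phys.ring_radii[0]
        x, y = to_mile_plane(Placement("m", 0, -r1, "physical"), cal_phys)
        assert x == pytest.approx(0.0, abs=1e-9)
        assert y == pytest.approx(10.0)

    def test_radius_matches_center_distance(self, cal_phys):
        rng = np.random.default_rng(2)
        for _ in range(20):
            px, py = rng.uniform(-600, 600, size=2)
            p = Placement("m", px, py, "physical")
            x, y = to_mile_plane(p, cal_phys)
            assert math.hypot(x, y) == pytest.approx(
                pixels_to_miles(radial_distance(p, cal_phys), cal_phys), rel=1e-9
            )


class TestPairwiseMileDistances:
    def test_colocated_figures_are_zero(self, cal_phys):
        rec = make_record({"mother": 100, "father": 100}, {"mother": 100, "father": 100})
        _, mat = pairwise_mile_distances(rec, cal_phys)
        assert mat == pytest.approx(np.zeros((2, 2)))

    def test_opposite_points_sum_radii(self, cal_phys):
        # (0, 10) and (0, -10) in the mile plane are 20 miles apart.
        r1 = cal_phys.ring_radii[0]
        rec = make_record(
            {"mother": 50, "father": 50},
            {"mother": r1, "father": r1},
            angles={"mother": math.pi / 2, "father": -math.pi / 2},
        )
        _, mat = pairwise_mile_distances(rec, cal_phys)
        assert mat[0, 1] == pytest.approx(20.0)

    def test_matches_brute_force_double_loop(self, cal_phys):
        rng = np.random.default_rng(3)
        roles = ["mother", "father", "sibling", "friend", "other"]
        radii = dict(zip(roles, rng.uniform(0, 650, 5)))
        angles = dict(zip(roles, rng.uniform(0, 2 * math.pi, 5)))
        rec = make_record({r: 100 for r in roles}, radii, angles=angles)
        out_roles, mat = pairwise_mile_distances(rec, cal_phys)
        pts = {
            p.role: to_mile_plane(p, cal_phys) for p in rec.physical
        }
        for i, a in enumerate(out_roles):
            for j, b in enumerate(out_roles):
                expect = math.hypot(pts[a][0] - pts[b][0], pts[a][1] - pts[b][1])
                assert mat[i, j] == pytest.approx(expect, abs=1e-9)

    def test_symmetry_zero_diagonal_triangle_inequality(self, cal_phys):
        rng = np.random.default_rng(4)
        roles = ["mother", "father", "sibling", "friend", "other"]
        rec = make_record(
            {r: 100 for r in roles},
            dict(zip(roles, rng.uniform(0, 650, 5))),
            angles=dict(zip(roles, rng.uniform(0, 2 * math.pi, 5))),
        )
        _, m = pairwise_mile_distances(rec, cal_phys)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        n = m.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9


class TestDomainTypes:
    def test_ring_radii_must_increase(self):
        with pytest.raises(CalibrationError):
            DiagramCalibration(kind="emotional", ring_radii=(380.0, 60.0, 700.0))

    def test_emotional_rejects_mile_anchors(self):
        with pytest.raises(CalibrationError):
            DiagramCalibration(kind="emotional", ring_miles=(10.0, 250.0, 500.0))

    def test_physical_requires_mile_anchors(self):
        with pytest.raises(CalibrationError):
            DiagramCalibration(kind="physical", ring_miles=None)

    def test_record_role_sets_must_match(self):
        with pytest.raises(ValidationError):
            make_record({"mother": 50}, {"father": 50})

    def test_underage_rejected_unless_permitted(self):
        with pytest.raises(ValidationError):
            make_record({"mother": 50}, age=20)

    @pytest.mark.parametrize(
        "age,expected",
        [(24, "early_adulthood"), (34, "early_adulthood"), (35, "early_middle"),
         (44, "early_middle"), (45, "late_middle"), (64, "late_middle"),
         (65, "late_adulthood"), (99, "late_adulthood")],
    )
    def test_age_bins_partition(self, age, expected):
        assert age_group(age) == expected

    def test_age_below_inclusion_raises(self):
        with pytest.raises(InputError):
            age_group(20)

    @pytest.mark.parametrize(
        "raw,expected",
        [("Best Friend", "friend"), ("daughter", "child"), ("son", "child"),
         ("Sister", "sibling"), ("romantic partner", "romantic_partner"),
         ("grandmother", "other"), ("mother", "mother"), ("unheard-of role", "other")],
    )
    def test_role_collapse(self, raw, expected):
        assert collapse_role(raw) == expected
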