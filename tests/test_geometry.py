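"""Contour area and slice-stack volumetry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eatq.geometry import (
    Contour,
    ContourStack,
    ContourValidationError,
    EmptyMeasurementError,
    polygon_area,
    slice_area,
    stack_volume,
    volume_to_mass,
)
from eatq.phantom import PhantomSpec, generate_phantom, truncated_ellipsoid_volume_ml

from conftest import square


def mc_area(points, n_samples=200_000, seed=42):
    """Monte-Carlo point-in-polygon area oracle (even-odd ray casting)."""
    pts = np.asarray(points, dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, 2))
    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    px = samples[:, 0][:, None]
    py = samples[:, 1][:, None]
    crosses = ((y1 <= py) != (y2 <= py)) & (
        px < x1 + (py - y1) * (x2 - x1) / np.where(y2 == y1, np.inf, y2 - y1)
    )
    inside = crosses.sum(axis=1) % 2 == 1
    box = np.prod(hi - lo)
    p = inside.mean()
    return p * box, math.sqrt(p * (1 - p) / n_samples) * box


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(square()) == pytest.approx(1.0)

    def test_orientation_independent(self):
        assert polygon_area(square(clockwise=True)) == pytest.approx(1.0)

    def test_regular_720gon_matches_circle(self):
        t = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        c = Contour(
            points=np.column_stack([10 * np.cos(t), 10 * np.sin(t)]),
            slice_index=0, phase="end_diastole", structure="eat",
        )
        area = polygon_area(c)
        assert area == pytest.approx(math.pi * 100, rel=1e-4)
        est, se = mc_area(c.points, n_samples=100_000)
        assert abs(area - est) < 3 * se

    @pytest.mark.parametrize("seed", range(5))
    def test_monte_carlo_oracle_random_star_polygons(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        angles = np.sort(rng.uniform(0, 2 * math.pi, n))
        radii = rng.uniform(5, 30, n)
        pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        c = Contour(points=pts, slice_index=0, phase="end_diastole", structure="eat")
        est, se = mc_area(pts, seed=seed + 1)
        assert abs(polygon_area(c) - est) < 3 * se

    @given(
        angle=st.floats(0, 2 * math.pi),
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
    )
    @settings(deadline=None, max_examples=50)
    def test_rigid_transform_invariance(self, angle, dx, dy):
        base = np.array([(0, 0), (7, 1), (9, 6), (4, 9), (-1, 4)], dtype=float)
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = base @ rot.T + (dx, dy)
        a0 = polygon_area(Contour(base, 0, "end_diastole", "eat"))
        a1 = polygon_area(Contour(moved, 0, "end_diastole", "eat"))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ContourValidationError, match="slice=3"):
            Contour(np.array([(0.0, 0.0), (1.0, 1.0)]), 3, "end_diastole", "eat")

    def test_self_intersection_rejected(self):
        bowtie = np.array([(0, 0), (1, 1), (1, 0), (0, 1)], dtype=float)
        with pytest.raises(ContourValidationError, match="self-intersecting"):
            Contour(bowtie, 0, "end_diastole", "lv_endo")

    def test_collinear_zero_area_rejected(self):
        line = np.array([(0, 0), (1, 1), (2, 2), (3, 3)], dtype=float)
        with pytest.raises(ContourValidationError):
            Contour(line, 0, "end_diastole", "eat")

    def test_duplicate_points_deduplicated(self):
        pts = np.array([(0, 0), (0, 0), (1, 0), (1, 1), (0, 1), (0, 0)], dtype=float)
        c = Contour(pts, 0, "end_diastole", "eat")
        assert len(c.points) == 4
        assert polygon_area(c) == pytest.approx(1.0)


class TestSliceArea:
    def test_disjoint_patches_add(self):
        patches = [square(), square(origin=(5.0, 5.0))]
        assert slice_area(patches) == pytest.approx(2.0)

    def test_hole_subtracted(self):
        outer = square(side=10.0)
        hole = square(side=2.0, origin=(4.0, 4.0), role="hole")
        assert slice_area([outer, hole]) == pytest.approx(96.0)

    def test_empty_slice_is_zero(self):
        assert slice_area([]) == 0.0

    def test_hole_exceeding_outer_rejected(self):
        outer = square(side=1.0)
        hole = square(side=10.0, origin=(-4.0, -4.0), role="hole")
        with pytest.raises(ContourValidationError, match="exceeds outer"):
            slice_area([outer, hole])

    def test_mixed_slices_rejected(self):
        with pytest.raises(ContourValidationError, match="multiple"):
            slice_area([square(), square(slice_index=1)])


class TestStackVolume:
    def test_constant_area_prism(self, prism_stack):
        res = stack_volume(prism_stack, "eat", "end_diastole")
        assert res.volume_ml == pytest.approx(30.0, abs=1e-9)
        assert res.per_slice_areas_mm2 == pytest.approx(np.full(10, 500.0))

    def test_single_slice(self, prism_stack):
        stack = ContourStack(
            contours=[prism_stack.contours[0]],
            slice_thickness_mm=5.0, inter_slice_gap_mm=1.0, n_slices=1,
        )
        # 500 mm^2 x 6 mm = 3 ml
        assert stack_volume(stack, "eat", "end_diastole").volume_ml == pytest.approx(3.0)

    def test_empty_measurement_is_an_error(self, prism_stack):
        with pytest.raises(EmptyMeasurementError, match="lv_endo"):
            stack_volume(prism_stack, "lv_endo", "end_diastole")

    def test_ellipsoid_within_2pct_at_2mm_spacing(self):
        spec = PhantomSpec(
            endo_semi_axes_mm=(30, 25, 20), wall_thickness_mm=5, fat_thickness_mm=0,
            slice_thickness_mm=1.0, inter_slice_gap_mm=1.0, es_scale=1.0,
        )
        stack, _ = generate_phantom(spec)
        analytic = 4 / 3 * math.pi * 30 * 25 * 20 / 1000
        assert analytic == pytest.approx(62.83, abs=0.01)
        measured = stack_volume(stack, "lv_endo", "end_diastole").volume_ml
        assert measured == pytest.approx(analytic, rel=0.02)

    def test_convergence_with_spacing(self):
        analytic = truncated_ellipsoid_volume_ml((30, 25, 20))
        errors = []
        for spacing in (8.0, 4.0, 2.0):
            spec = PhantomSpec(
                endo_semi_axes_mm=(30, 25, 20), wall_thickness_mm=5, fat_thickness_mm=0,
                slice_thickness_mm=spacing / 2, inter_slice_gap_mm=spacing / 2,
                vertices_per_contour=256,
            )
            stack, _ = generate_phantom(spec)
            v = stack_volume(stack, "lv_endo", "end_diastole").volume_ml
            errors.append(abs(v - analytic) / analytic)
        assert errors[-1] <= 0.02
        assert errors[2] <= errors[0]


class TestVolumeToMass:
    def test_fat_density(self):
        assert volume_to_mass(100.0, 0.92) == pytest.approx(92.0)

    def test_zero_volume(self):
        assert volume_to_mass(0.0, 0.92) == 0.0

    def test_chf_mean_volume(self):
        assert volume_to_mass(46.0, 0.92) == pytest.approx(42.32)

    def test_negative_volume_rejected(self):
        with pytest.raises(ContourValidationError):
            volume_to_mass(-1.0, 0.92)

    @given(
        volume=st.floats(0, 1e4, allow_nan=False),
        density=st.floats(0.1, 5.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_linearity(self, volume, density):
        assert volume_to_mass(volume, density) == density * volume
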