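"""Shape-descriptor unit and property tests against analytic oracles."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from clearmorph.morphometry import (
    MIN_FIT_VOXELS,
    classify_phenotype,
    compute_surface_area,
    compute_volume,
    fit_ellipsoid,
    measure_all,
    oblate_ellipticity,
    prolate_ellipticity,
    sphericity,
)

VS = (1.0, 0.5, 0.5)  # default anisotropic voxel size, µm


axis_triples = st.tuples(
    st.floats(0.5, 50), st.floats(0.5, 50), st.floats(0.5, 50)
).map(lambda t: tuple(sorted(t)))


class TestFormulas:
    def test_sphere_is_perfectly_spherical(self):
        r = 3.7
        v = 4 / 3 * np.pi * r**3
        a = 4 * np.pi * r**2
        assert sphericity(v, a) == pytest.approx(1.0, abs=1e-12)

    def test_cube_sphericity_matches_closed_form(self):
        s = 2.0
        assert sphericity(s**3, 6 * s**2) == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-12)

    def test_sphere_limit_of_ellipticities_is_zero(self):
        assert prolate_ellipticity(2, 2, 2) == pytest.approx(0.0, abs=1e-15)
        assert oblate_ellipticity(2, 2, 2) == pytest.approx(0.0, abs=1e-15)

    def test_needle_limit_of_prolate_is_one(self):
        assert prolate_ellipticity(1, 1, 10) == pytest.approx(0.99, abs=1e-12)
        assert prolate_ellipticity(1, 1, 1e6) == pytest.approx(1.0, abs=1e-6)

    def test_pancake_limit_of_oblate_is_one(self):
        assert oblate_ellipticity(1, 10, 10) == pytest.approx(0.99, abs=1e-12)
        assert oblate_ellipticity(1e-6, 1, 1) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("fn", [prolate_ellipticity, oblate_ellipticity])
    def test_unsorted_or_nonpositive_axes_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(3, 2, 1)
        with pytest.raises(ValueError):
            fn(0, 1, 2)

    def test_sphericity_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            sphericity(1.0, -1.0)

    @given(axis_triples)
    def test_ellipticities_lie_in_unit_interval(self, axes):
        a, b, c = axes
        for val in (prolate_ellipticity(a, b, c), oblate_ellipticity(a, b, c)):
            assert 0.0 <= val < 1.0

    @given(st.floats(0.5, 20), st.floats(1.001, 5), st.floats(0.1, 10))
    def test_scale_invariance_of_all_descriptors(self, a, stretch, k):
        """Multiplying every physical dimension by k changes nothing."""
        b, c = a * stretch, a * stretch**2
        assert prolate_ellipticity(a * k, b * k, c * k) == pytest.approx(
            prolate_ellipticity(a, b, c), rel=1e-9
        )
        assert oblate_ellipticity(a * k, b * k, c * k) == pytest.approx(
            oblate_ellipticity(a, b, c), rel=1e-9
        )
        v, s = 4 / 3 * np.pi * a * b * c, oracles.ellipsoid_surface_area(a, b, c)
        assert sphericity(v * k**3, s * k**2) == pytest.approx(sphericity(v, s), rel=1e-9)

    @given(axis_triples)
    def test_matches_exact_rational_oracle(self, axes):
        a, b, c = (Fraction(round(x * 1024), 1024) for x in axes)
        if not 0 < a <= b <= c:
            return
        assert prolate_ellipticity(float(a), float(b), float(c)) == pytest.approx(
            float(oracles.frac_prolate(a, b, c)), abs=1e-12
        )
        assert oblate_ellipticity(float(a), float(b), float(c)) == pytest.approx(
            float(oracles.frac_oblate(a, b, c)), abs=1e-12
        )


class TestVoxelMeasures:
    def test_volume_is_count_times_voxel_volume(self):
        idx = np.argwhere(np.ones((10, 10, 10), bool))
        assert compute_volume(idx, VS) == pytest.approx(1000 * 0.25)

    def test_empty_object_has_no_volume_or_area(self):
        with pytest.raises(ValueError):
            compute_volume(np.empty((0, 3)), VS)
        with pytest.raises(ValueError):
            compute_surface_area(np.empty((0, 3)), VS)

    def test_voxelized_sphere_volume_near_analytic(self):
        mask = oracles.rasterize_ellipsoid_mask((10, 10, 10), VS)
        idx = np.argwhere(mask)
        assert compute_volume(idx, VS) == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)

    def test_voxelized_sphere_area_near_analytic(self):
        vs = (0.5, 0.5, 0.5)
        mask = oracles.rasterize_ellipsoid_mask((10, 10, 10), vs)
        area, flags = compute_surface_area(np.argwhere(mask), vs)
        assert flags == []
        assert area == pytest.approx(4 * np.pi * 100, rel=0.03)

    def test_single_voxel_face_area_fallback(self):
        area, flags = compute_surface_area(np.array([[0, 0, 0]]), (0.5, 0.5, 0.5))
        assert area == pytest.approx(6 * 0.25)
        assert "face_area_fallback" in flags

    def test_area_converges_toward_analytic_with_resolution(self):
        """The coarse-grid area error shrinks when voxels shrink."""
        true = 4 * np.pi * 36
        errs = []
        for h in (1.0, 0.5):
            mask = oracles.rasterize_ellipsoid_mask((6, 6, 6), (h, h, h))
            area, _ = compute_surface_area(np.argwhere(mask), (h, h, h))
            errs.append(abs(area - true) / true)
        assert errs[1] < errs[0]


class TestEllipsoidFit:
    def test_recovers_axis_aligned_ellipsoid(self):
        mask = oracles.rasterize_ellipsoid_mask((30, 15, 10), VS)  # (z,y,x) extents
        axes, _, flags = fit_ellipsoid(np.argwhere(mask), VS)
        assert flags == []
        for got, want in zip(axes, (10, 15, 30)):
            assert got == pytest.approx(want, rel=0.05)

    def test_rotation_invariance(self):
        th = np.deg2rad(45)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        mask = oracles.rasterize_ellipsoid_mask((10, 15, 30), VS, rotation=rot, pad_um=4)
        axes, _, _ = fit_ellipsoid(np.argwhere(mask), VS)
        for got, want in zip(axes, (10, 15, 30)):
            assert got == pytest.approx(want, rel=0.05)

    def test_sphere_has_three_equal_axes(self):
        mask = oracles.rasterize_ellipsoid_mask((8, 8, 8), VS)
        (a, b, c), _, _ = fit_ellipsoid(np.argwhere(mask), VS)
        assert c / a == pytest.approx(1.0, abs=0.03)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipsoid(np.zeros((MIN_FIT_VOXELS - 1, 3)), VS)

    def test_coplanar_object_floored_and_flagged(self):
        idx = np.argwhere(np.ones((1, 10, 10), bool))  # single z-slice
        axes, _, flags = fit_ellipsoid(idx, VS)
        assert "degenerate_axis" in flags
        assert axes[0] == pytest.approx(0.25)  # half the smallest voxel extent


class TestClassification:
    @pytest.mark.parametrize(
        "e_ob, e_pro, want",
        [
            (0.8, 0.1, "oblate_dominant_M1like"),
            (0.1, 0.8, "prolate_dominant_M2like"),
            (0.4, 0.4, "indeterminate"),
            (0.42, 0.4, "indeterminate"),  # inside the 0.05 tie band
        ],
    )
    def test_phenotype_margin(self, e_ob, e_pro, want):
        assert classify_phenotype(e_pro, e_ob) == want


class TestMeasureAll:
    def test_empty_volume_yields_empty_collection(self):
        from clearmorph.segmentation import LabeledVolume

        lv = LabeledVolume(
            labels=np.zeros((4, 4, 4), np.int32), voxel_size=VS, counts=np.array([], np.int64)
        )
        assert measure_all(lv) == []

    def test_scene_measures_match_ground_truth(self, clean_scene):
        from clearmorph.segmentation import SegmentationParams, segment_cells, subtract_background

        spec, stack, truth = clean_scene
        lv = segment_cells(subtract_background(stack, 10.0), SegmentationParams())
        records = measure_all(lv)
        assert len(records) == len(truth.cells())
        assert [r.object_id for r in records] == sorted(r.object_id for r in records)
        got = np.mean([r.volume_um3 for r in records])
        want = np.mean([o.volume_um3 for o in truth.cells()])
        assert got == pytest.approx(want, rel=0.05)
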