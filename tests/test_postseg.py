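"""Post-segmentation metrics: hand-computed series, boundary semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from spheroseg import (
    CutoffResult,
    CutoffRule,
    LabelVolume,
    SpheroidVolume,
    ThresholdPolicy,
    VoxelGeometry,
    apply_cutoff,
    approximate_height,
    bin_regions,
    classify_positive,
    clearing_metric,
    nuclear_segmentation_cutoff,
)
from spheroseg.nuclei import NucleusRecord

ISO = VoxelGeometry(dx=1.0, dy=1.0, dz=1.0)


class TestApproximateHeight:
    def test_worked_example(self):
        # max at plane 3 (1-based), dz = 5 -> height 2 * 3 * 5 = 30
        assert approximate_height(np.array([1, 4, 9, 4, 1]), dz=5.0) == 30.0

    def test_monotonic_increase_undefined(self):
        assert approximate_height(np.array([1, 2, 3, 4, 5]), dz=5.0) is None

    def test_single_plane_undefined(self):
        assert approximate_height(np.array([9.0]), dz=5.0) is None

    def test_decay_gate_uses_planes_after_max_only(self):
        # decay on the near side is irrelevant; after the max the area never
        # falls below 0.97 x max -> undefined
        assert approximate_height(np.array([1.0, 9.0, 8.95, 8.50]), dz=5.0) == 20.0
        assert approximate_height(np.array([1.0, 9.0, 8.95, 8.93]), dz=5.0) is None

    def test_empty_or_zero(self):
        assert approximate_height(np.array([]), dz=5.0) is None
        assert approximate_height(np.zeros(5), dz=5.0) is None

    @given(st.integers(2, 12), st.integers(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_height_is_twice_max_plane_depth(self, n_after, k0):
        rising = list(np.linspace(1.0, 9.0, k0, endpoint=False))
        falling = list(np.linspace(8.0, 2.0, n_after))
        areas = rising + [10.0] + falling
        h = approximate_height(np.array(areas), dz=5.0)
        assert h == 2.0 * (k0 + 1) * 5.0


def _volumes_from_series(nuc_area_vox, sph_area_vox, ny=12, nx=100):
    """Build label + spheroid volumes whose per-plane voxel areas are given."""
    nz = len(nuc_area_vox)
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for zi, (na, sa) in enumerate(zip(nuc_area_vox, sph_area_vox)):
        flat_s = np.zeros(ny * nx, dtype=bool)
        flat_s[:sa] = True
        mask[zi] = flat_s.reshape(ny, nx)
        flat_n = np.zeros(ny * nx, dtype=np.int32)
        flat_n[:na] = 1
        labels[zi] = flat_n.reshape(ny, nx)
    sph = SpheroidVolume(
        mask=mask,
        slice_area=mask.sum(axis=(1, 2)) * ISO.pixel_area,
        edge_distance=ndimage.distance_transform_edt(mask, sampling=ISO.sampling_zyx),
        geometry=ISO,
    )
    return LabelVolume(labels, ISO), sph


class TestNuclearSegmentationCutoff:
    def test_fifty_percent_rule_on_given_ratio(self):
        # ratio sequence 0.6 0.6 0.6 0.25 0.1, window 1 (no extra smoothing):
        # max 0.6, half 0.3, first below at plane 4 (1-based)
        nuc = [60, 60, 60, 25, 10]
        sph = [100] * 5
        labels, spheroid = _volumes_from_series(nuc, sph)
        result = nuclear_segmentation_cutoff(labels, spheroid, smoothing_window=1)
        assert result.cutoff_slice == 4
        assert result.cutoff_rule_used == CutoffRule.FIFTY_PERCENT
        np.testing.assert_allclose(result.ratio_per_slice,
                                   [0.6, 0.6, 0.6, 0.25, 0.1])

    def test_area_fallback_when_ratio_constant(self):
        # constant coverage, spheroid area collapsing below 10% of max at
        # the last plane -> fallback rule fires there
        sph = [100, 100, 100, 100, 100, 80, 50, 30, 20, 5]
        nuc = [int(0.6 * a) for a in sph]
        labels, spheroid = _volumes_from_series(nuc, sph)
        result = nuclear_segmentation_cutoff(labels, spheroid, smoothing_window=1)
        assert result.cutoff_slice == 10
        assert result.cutoff_rule_used == CutoffRule.TEN_PERCENT_AREA_FALLBACK

    def test_no_rule_fires_keeps_full_stack(self):
        sph = [100, 100, 100, 100]
        nuc = [60, 60, 58, 60]
        labels, spheroid = _volumes_from_series(nuc, sph)
        result = nuclear_segmentation_cutoff(labels, spheroid)
        assert result.cutoff_slice is None
        assert result.cutoff_rule_used == CutoffRule.NONE

    def test_ratio_bounded_by_one_when_nuclei_inside_spheroid(
        self, default_analysis
    ):
        ratio = default_analysis.cutoff.ratio_per_slice
        finite = ratio[np.isfinite(ratio)]
        assert finite.min() >= 0.0
        assert finite.max() <= 1.05

    def test_even_window_rejected(self):
        labels, spheroid = _volumes_from_series([10, 10], [20, 20])
        with pytest.raises(ValueError):
            nuclear_segmentation_cutoff(labels, spheroid, smoothing_window=2)


class TestClearingMetric:
    def _cutoff(self, plane):
        return CutoffResult(np.array([]), np.array([]), plane,
                            CutoffRule.FIFTY_PERCENT)

    def test_simple_ratio(self):
        summary = clearing_metric(self._cutoff(20), height_um=200.0, dz=5.0)
        assert summary.clearing_metric == pytest.approx(0.5)
        assert not summary.excluded_over_one

    def test_over_one_excluded(self):
        summary = clearing_metric(self._cutoff(42), height_um=200.0, dz=5.0)
        assert summary.cutoff_depth == 210.0
        assert summary.clearing_metric is None
        assert summary.excluded_over_one

    def test_undefined_height_still_reports_cutoff(self):
        summary = clearing_metric(self._cutoff(20), height_um=None, dz=5.0)
        assert summary.clearing_metric is None
        assert summary.cutoff_depth == 100.0
        assert not summary.excluded_over_one


def _record(z_um, distance=np.nan, intensity=None):
    return NucleusRecord(
        label=1, centroid=(10.0, 10.0, z_um), volume=500.0, voxel_count=250,
        mean_intensity={"2": intensity} if intensity is not None else {},
        distance_to_edge=distance, z_slice_span=(0, 1), provenance="primary",
    )


class TestApplyCutoff:
    def test_strictly_below_depth_retained(self):
        cutoff = CutoffResult(np.array([]), np.array([]), 20,
                              CutoffRule.FIFTY_PERCENT)  # depth 100 um
        records = [_record(50.0), _record(99.9), _record(100.1)]
        kept = apply_cutoff(records, cutoff, dz=5.0)
        assert [r.centroid[2] for r in kept] == [50.0, 99.9]

    def test_undefined_cutoff_is_identity(self):
        cutoff = CutoffResult(np.array([]), np.array([]), None, CutoffRule.NONE)
        records = [_record(50.0), _record(500.0)]
        assert apply_cutoff(records, cutoff, dz=5.0) == records

    def test_all_deeper_gives_empty(self):
        cutoff = CutoffResult(np.array([]), np.array([]), 2,
                              CutoffRule.FIFTY_PERCENT)
        assert apply_cutoff([_record(50.0)], cutoff, dz=5.0) == []


class TestClassifyPositive:
    def test_all_below_threshold(self):
        records = [_record(10, intensity=v) for v in (100.0, 200.0)]
        flags, frac = classify_positive(records, "2", threshold=500.0)
        assert flags == [False, False] and frac == 0.0

    def test_boundary_is_positive(self):
        records = [_record(10, intensity=500.0)]
        flags, frac = classify_positive(records, "2", threshold=500.0)
        assert flags == [True] and frac == 1.0

    def test_empty_records(self):
        assert classify_positive([], "2", 1.0) == ([], 0.0)

    def test_fraction_invariant_under_rescaled_controls(self):
        rng = np.random.default_rng(5)
        controls = rng.uniform(2000, 4000, 300)
        records = [_record(10, intensity=v)
                   for v in rng.uniform(50, 4000, 200)]
        policy = ThresholdPolicy()
        thr = policy.resolve(controls)
        _, frac = classify_positive(records, "2", thr)
        scale = 7.5
        scaled_records = [_record(10, intensity=r.mean_intensity["2"] * scale)
                          for r in records]
        thr_scaled = policy.resolve(controls * scale)
        _, frac_scaled = classify_positive(scaled_records, "2", thr_scaled)
        assert frac_scaled == frac

    def test_control_policy_requires_controls(self):
        with pytest.raises(ValueError, match="control"):
            ThresholdPolicy().resolve(None)
        with pytest.raises(ValueError, match="value"):
            ThresholdPolicy(mode="fixed").resolve()


class TestBinRegions:
    def _spheroid(self):
        mask = np.ones((40, 30, 30), dtype=bool)
        return SpheroidVolume(
            mask=mask,
            slice_area=mask.sum(axis=(1, 2)) * ISO.pixel_area,
            edge_distance=ndimage.distance_transform_edt(mask,
                                                         sampling=(1.0, 1.0, 1.0)),
            geometry=ISO,
        )

    def test_depth_bin_boundaries(self):
        records = [_record(59.9), _record(60.0), _record(120.0), _record(120.1)]
        bins = bin_regions(records, self._spheroid())
        assert bins.depth_bin == ["bottom", "middle", "middle", "top"]

    def test_outer_layer_inclusive_at_12_8(self):
        records = [_record(10, distance=12.8), _record(10, distance=12.9),
                   _record(10, distance=0.0)]
        bins = bin_regions(records, self._spheroid())
        assert bins.layer_bin == ["outer", "inner", "outer"]

    def test_bins_partition_records(self):
        rng = np.random.default_rng(0)
        records = [_record(float(z), distance=float(d))
                   for z, d in zip(rng.uniform(0, 200, 50), rng.uniform(0, 40, 50))]
        bins = bin_regions(records, self._spheroid())
        assert len(bins.depth_bin) == len(bins.layer_bin) == 50
        assert set(bins.depth_bin) <= {"bottom", "middle", "top"}
        assert set(bins.layer_bin) <= {"outer", "inner"}

    def test_outer_fraction_shrinks_with_radius(self):
        # shell-to-core ratio falls as r^2/r^3: a bigger spheroid has a
        # smaller outer-layer fraction at fixed 12.8 um shell depth
        def outer_fraction(radius):
            rng = np.random.default_rng(1)
            n = 400
            pts = rng.normal(size=(4 * n, 3))
            pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
            pts *= rng.uniform(0, 1, (4 * n, 1)) ** (1 / 3) * radius
            center = np.array([radius + 15.0] * 3)
            mask_r = int(radius + 10)
            shape = (2 * mask_r + 10,) * 3
            zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
            ball = ((zz + 0.5 - center[2]) ** 2 + (yy + 0.5 - center[1]) ** 2
                    + (xx + 0.5 - center[0]) ** 2) <= radius**2
            sph = SpheroidVolume(
                mask=ball,
                slice_area=ball.sum(axis=(1, 2)) * ISO.pixel_area,
                edge_distance=ndimage.distance_transform_edt(
                    ball, sampling=(1.0, 1.0, 1.0)),
                geometry=ISO,
            )
            records = [_record(0.0) for _ in range(n)]
            for r, p in zip(records, pts[:n]):
                r.centroid = tuple(p + center)
            bins = bin_regions(records, sph)
            return bins.layer_bin.count("outer") / n

        assert outer_fraction(50.0) > outer_fraction(80.0)
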