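"""Nuclear segmentation: smoothing, PNVs, watershed, sorting, full pipeline."""

import heapq

import numpy as np
import pytest
from scipy import ndimage

from spheroseg import (
    ImageStack,
    LabelVolume,
    SegParams,
    SyntheticSpec,
    VoxelGeometry,
    WellImageSet,
    classify_volumes,
    detect_pnvs,
    generate_spheroid,
    segment_nuclei,
    smooth,
    split_by_watershed,
)
from spheroseg.gate import gate_and_crop, rough_spheroid_mask
from spheroseg.nuclei import _hminima
from spheroseg.synthetic import CHANNEL_NUCLEI

from conftest import assert_labels_contiguous

ISO = VoxelGeometry(dx=1.0, dy=1.0, dz=1.0)


def _ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz + 0.5) * spacing[0] - center[0]) ** 2
        + ((yy + 0.5) * spacing[1] - center[1]) ** 2
        + ((xx + 0.5) * spacing[2] - center[2]) ** 2
    ) <= radius**2


class TestSmooth:
    def test_zero_sigma_is_identity(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.integers(0, 4000, (4, 20, 20)).astype(np.uint16))
        out = smooth(stack, SegParams(gaussian_sigma_xy=0.0, gaussian_sigma_z=0.0))
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_impulse_mass_conserved(self):
        voxels = np.zeros((9, 41, 41))
        voxels[4, 20, 20] = 1000.0
        out = smooth(ImageStack(voxels), SegParams())
        assert out.voxels.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_nucleolus_dip_removed(self):
        from skimage.morphology import local_minima

        spec = SyntheticSpec(
            n_nuclei=1, spheroid_radius=18.0, margin_xy=12.0,
            gaussian_noise_sd=0.0, nucleolus_contrast=0.4, intensity_cv=0.0,
            nucleus_diameter_sd=0.0, seed=3,
        )
        well, _ = generate_spheroid(spec)
        stack = well.channel(CHANNEL_NUCLEI)

        def interior_minima(sigma):
            sm = smooth(stack, SegParams(gaussian_sigma_xy=sigma,
                                         gaussian_sigma_z=sigma)).voxels
            zi = np.unravel_index(np.argmax(sm), sm.shape)[0]
            plane = sm[zi]
            core = ndimage.binary_erosion(plane > 0.4 * plane.max(),
                                          np.ones((3, 3)), iterations=2)
            return int((local_minima(plane) & core).sum())

        # barely smoothed, the dim nucleolus is an interior local minimum
        assert interior_minima(0.3) >= 1
        # at the working sigma it is gone entirely
        assert interior_minima(2.0) == 0


class TestDetectPnvs:
    def _isolated_nucleus(self):
        spec = SyntheticSpec(
            n_nuclei=1, spheroid_radius=18.0, margin_xy=12.0,
            gaussian_noise_sd=0.0, nucleolus_contrast=0.0, intensity_cv=0.0,
            nucleus_diameter_sd=0.0, seed=5,
        )
        return generate_spheroid(spec)

    def test_isolated_nucleus_recovered(self):
        well, truth = self._isolated_nucleus()
        stack = well.channel(CHANNEL_NUCLEI)
        params = SegParams()
        pnvs = detect_pnvs(smooth(stack, params), params)
        assert pnvs.n_objects == 1
        # the watershed-filled output covers most of the rendered nucleus
        out = split_by_watershed(pnvs, params.hmin_primary)
        rendered = stack.voxels > 0.25 * stack.voxels.max()
        covered = (out.labels > 0) & rendered
        assert covered.sum() >= 0.8 * rendered.sum()

    def test_intensity_scale_invariance(self):
        well, _ = self._isolated_nucleus()
        stack = well.channel(CHANNEL_NUCLEI)
        params = SegParams()
        sm = smooth(stack, params)
        p1 = detect_pnvs(sm, params)
        p4 = detect_pnvs(ImageStack(sm.voxels * 4.0, sm.geometry), params)
        np.testing.assert_array_equal(p1.labels, p4.labels)

    def test_touching_ellipsoids_undersegmented(self):
        # two spheres overlapping by 30% of a radius, constant interior
        # intensity and no seam: nothing separates them at the edge stage
        g = VoxelGeometry()
        r, gap = 5.8, 1.7 * 5.8
        shape = (9, 64, 64)
        c = np.array([22.5, 20.0, 16.0])  # z, y, x um
        m1 = _ball_mask(shape, (c[0], c[1], c[2]), r, g.sampling_zyx)
        m2 = _ball_mask(shape, (c[0], c[1], c[2] + gap), r, g.sampling_zyx)
        voxels = np.where(m1 | m2, 3000.0, 0.0)
        voxels = ndimage.gaussian_filter(voxels, (1.5 / g.dz, 0.8 / g.dy, 0.8 / g.dx))
        params = SegParams()
        pnvs = detect_pnvs(smooth(ImageStack(voxels, g), params), params)
        assert pnvs.n_objects == 1


def flood_oracle(surface, markers, mask):
    """Independent priority-flood watershed (26-connectivity).

    Floods from the markers, always extending from the lowest-surface
    front voxel, first-come-first-served on plateaus.
    """
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    out = np.zeros_like(markers)
    heap = []
    age = 0
    for idx in zip(*np.nonzero(markers)):
        out[idx] = markers[idx]
        heapq.heappush(heap, (surface[idx], age, idx))
        age += 1
    shape = surface.shape
    while heap:
        _, _, idx = heapq.heappop(heap)
        label = out[idx]
        for dz, dy, dx in offsets:
            nb = (idx[0] + dz, idx[1] + dy, idx[2] + dx)
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]):
                continue
            if mask[nb] and out[nb] == 0:
                out[nb] = label
                heapq.heappush(heap, (surface[nb], age, nb))
                age += 1
    return out


def _dumbbell(r=8.0, d=12.0, shape=(32, 32, 32)):
    c = shape[2] / 2.0
    m1 = _ball_mask(shape, (c, c, c - d / 2.0), r)
    m2 = _ball_mask(shape, (c, c, c + d / 2.0), r)
    return LabelVolume((m1 | m2).astype(np.int32), ISO)


class TestSplitByWatershed:
    def test_single_sphere_single_label(self):
        pnv = LabelVolume(_ball_mask((24, 24, 24), (12, 12, 12), 9.0).astype(np.int32), ISO)
        out = split_by_watershed(pnv, hmin=1.0)
        assert out.n_objects == 1

    def test_dumbbell_splits_near_midplane(self):
        pnv = _dumbbell(r=8.0, d=12.0)
        out = split_by_watershed(pnv, hmin=1.0)
        assert out.n_objects == 2
        # the two sphere centres carry different labels
        la = out.labels[16, 16, 10]
        lb = out.labels[16, 16, 22]
        assert la != lb and la > 0 and lb > 0
        # along the axis, the split happens within 1 voxel of x = 16
        axis = out.labels[16, 16, :]
        transition = np.nonzero(np.diff(axis[axis > 0]))[0]
        xs = np.nonzero(axis > 0)[0]
        change_x = xs[transition[0] + 1]
        assert abs(change_x - 16) <= 1.5

    def test_hmin_above_neck_deficit_merges(self):
        # neck deficit = r - sqrt(r^2 - (d/2)^2) = 8 - 5.29 = 2.71 um
        pnv = _dumbbell(r=8.0, d=12.0)
        assert split_by_watershed(pnv, hmin=4.0).n_objects == 1

    @pytest.mark.parametrize("r,d", [(8.0, 12.0), (8.0, 10.0), (7.0, 11.0)])
    def test_matches_flood_oracle(self, r, d):
        pnv = _dumbbell(r=r, d=d)
        hmin = 1.0
        out = split_by_watershed(pnv, hmin=hmin)
        # rebuild the flooding surface exactly as the implementation defines
        # it, then flood with the independent oracle
        mask = pnv.labels > 0
        edt = ndimage.distance_transform_edt(mask, sampling=ISO.sampling_zyx)
        suppressed = _hminima(-edt, hmin)
        from skimage.morphology import local_minima

        minima = local_minima(suppressed, connectivity=3) & mask
        markers, _ = ndimage.label(minima, np.ones((3, 3, 3)))
        oracle = flood_oracle(suppressed, markers, mask)
        assert out.n_objects == oracle.max()
        # label-for-label agreement up to permutation
        agree = 0
        for lab in range(1, oracle.max() + 1):
            sel = oracle == lab
            vals, counts = np.unique(out.labels[sel], return_counts=True)
            agree += counts.max()
        assert agree == mask.sum()

    def test_partition_of_pnv(self):
        pnv = _dumbbell()
        out = split_by_watershed(pnv, hmin=1.0)
        assert not ((out.labels > 0) & (pnv.labels == 0)).any()
        assert ((pnv.labels > 0) & (out.labels == 0)).sum() == 0
        assert_labels_contiguous(out.labels)

    def test_label_count_monotone_in_hmin(self):
        pnv = _dumbbell(r=8.0, d=13.0)
        counts = [split_by_watershed(pnv, h).n_objects
                  for h in (0.25, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert counts == sorted(counts, reverse=True)


class TestClassifyVolumes:
    def _scene(self):
        labels = np.zeros((40, 82, 40), dtype=np.int32)
        labels[_ball_mask(labels.shape, (20, 20, 20), 5.8)] = 1    # ~817 um^3
        labels[_ball_mask(labels.shape, (20, 60, 20), 17.0)] = 2   # ~20600 um^3
        labels[4, 4, 4] = labels[4, 4, 5] = 3                      # debris
        return LabelVolume(labels, ISO)

    def test_sorting_rules(self):
        singles, clusters = classify_volumes(self._scene(), SegParams())
        assert singles.n_objects == 1
        assert clusters.n_objects == 1
        vol_single = (singles.labels > 0).sum()
        vol_cluster = (clusters.labels > 0).sum()
        assert vol_single == pytest.approx(817, rel=0.1)
        assert vol_cluster == pytest.approx(20580, rel=0.05)

    def test_debris_discarded(self):
        singles, clusters = classify_volumes(self._scene(), SegParams())
        kept = (singles.labels > 0) | (clusters.labels > 0)
        assert not kept[4, 4, 4] and not kept[4, 4, 5]


class TestSegmentNuclei:
    def _cropped_default(self, default_well):
        well, truth = default_well
        mask = rough_spheroid_mask(well.channel(CHANNEL_NUCLEI))
        result, cropped = gate_and_crop(well, mask)
        return cropped, truth, tuple(b[0] for b in result.bbox)

    def test_background_only_gives_no_records(self):
        stack = ImageStack(np.zeros((4, 32, 32), dtype=np.uint16))
        well = WellImageSet("p", "W", {"1": stack})
        labels, records = segment_nuclei(well)
        assert records == [] and labels.labels.max() == 0

    def test_missing_counterstain_fatal(self):
        stack = ImageStack(np.zeros((4, 32, 32), dtype=np.uint16))
        well = WellImageSet("p", "W", {"9": stack})
        with pytest.raises(KeyError, match="channel"):
            segment_nuclei(well, counterstain="1")

    def test_scale_invariant_labels_scaled_intensities(self, default_well):
        cropped, _, origin = self._cropped_default(default_well)
        labels1, recs1 = segment_nuclei(cropped, origin=origin)
        scaled = WellImageSet(
            cropped.plate_id, cropped.well_id,
            {ch: ImageStack(s.voxels.astype(np.float64) * 4.0, s.geometry)
             for ch, s in cropped.channels.items()},
        )
        labels4, recs4 = segment_nuclei(scaled, origin=origin)
        np.testing.assert_array_equal(labels1.labels, labels4.labels)
        for r1, r4 in zip(recs1, recs4):
            assert r4.mean_intensity["1"] == pytest.approx(4 * r1.mean_intensity["1"])
            assert r4.centroid == r1.centroid

    def test_records_consistent_with_labels(self, default_well):
        cropped, truth, origin = self._cropped_default(default_well)
        labels, records = segment_nuclei(cropped, origin=origin)
        assert_labels_contiguous(labels.labels)
        g = labels.geometry
        counts = np.bincount(labels.labels.ravel())
        for r in records:
            assert r.voxel_count == counts[r.label]
            assert r.volume == pytest.approx(r.voxel_count * g.voxel_volume)
            assert r.provenance in ("primary", "secondary")
        assert len(records) == labels.n_objects

    def test_secondary_pass_never_reduces_count(self, default_well):
        cropped, _, origin = self._cropped_default(default_well)
        _, with_secondary = segment_nuclei(cropped, SegParams(), origin=origin)
        _, primary_only = segment_nuclei(
            cropped, SegParams(max_secondary_rounds=0), origin=origin
        )
        assert len(with_secondary) >= len(primary_only)
        assert any(r.provenance == "secondary" for r in with_secondary)
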