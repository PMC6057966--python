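"""Marker-free 3D nuclear segmentation for cleared-spheroid stacks.

The pipeline is built around shape, not absolute brightness:

1. anisotropy-aware Gaussian smoothing suppresses sub-nuclear texture
   (dim nucleoli, bright pericentromeric foci) while keeping the intensity
   boundaries between neighbouring nuclei;
2. 2D (per-plane) and 3D Laplacian filters provide edge evidence; regions
   enclosed by the combined edges become potential nuclear volumes (PNVs).
   This stage is deliberately biased towards under-segmentation: touching
   nuclei may share one PNV.  Because only the *sign* of linear filters is
   used, the stage is invariant to rescaling the stack by any positive
   constant;
3. within each PNV, the complement of the physical-space Euclidean
   distance transform is H-minima suppressed and watershed-flooded,
   splitting multi-lobed clusters at their necks;
4. conditional volume/shape rules sort watershed objects into single
   nuclei (true nuclear volumes, TNVs) and residual clusters; residual
   clusters get one more, less aggressive (smaller H-minima depth)
   distance-transform watershed pass, and the TNVs of both passes are
   combined.

All distances are physical micrometres; the 5 um z-step therefore never
dominates the distance metric.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import local_minima, reconstruction
from skimage.segmentation import watershed

from .geometry import VoxelGeometry
from .stack_io import ImageStack, WellImageSet

STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def _sphere_volume(diameter_um: float) -> float:
    return (np.pi / 6.0) * diameter_um**3


@dataclass(frozen=True)
class SegParams:
    """Tunable parameters of the nuclear segmentation.

    Defaults are derived from the configured mean nuclear diameter
    (11.6 um): the single-nucleus volume window spans 1/8x to 8x the
    equivalent sphere volume, comfortably covering the +/- 2.2 um diameter
    SD.  ``hmin_secondary`` must be smaller than ``hmin_primary`` — the
    secondary pass is the less aggressive one, splitting residual clusters
    that survived the primary suppression depth.
    """

    gaussian_sigma_xy: float = 1.5       # um
    gaussian_sigma_z: float = 2.0        # um
    hmin_primary: float = 0.8            # um of distance-transform depth
    hmin_secondary: float = 0.4          # um; < hmin_primary
    nucleus_diameter_mean: float = 11.6  # um; anchors the volume window
    single_volume_range: tuple[float, float] | None = None  # um^3; None -> derived
    max_axis_ratio: float = 3.0
    min_compactness: float = 0.2         # volume / inertia-ellipsoid volume
    secondary_axis_ratio_relax: float = 1.5  # shape leniency in the final
                                             # sorting pass: a volume-window
                                             # object two watershed passes
                                             # could not split is most likely
                                             # one deformed nucleus
    pnv_min_voxels: int = 30             # edge-enclosed regions smaller than
                                         # this are speckle, not PNVs
    max_secondary_rounds: int = 1

    def __post_init__(self) -> None:
        if self.hmin_secondary >= self.hmin_primary:
            raise ValueError("hmin_secondary must be < hmin_primary")
        if self.gaussian_sigma_xy < 0 or self.gaussian_sigma_z < 0:
            raise ValueError("sigmas must be >= 0")
        lo, hi = self.resolved_volume_range
        if not lo < hi:
            raise ValueError("volume range min must be < max")

    @property
    def resolved_volume_range(self) -> tuple[float, float]:
        if self.single_volume_range is not None:
            return self.single_volume_range
        v = _sphere_volume(self.nucleus_diameter_mean)
        return (v / 8.0, v * 8.0)


@dataclass
class LabelVolume:
    """Integer label grid: 0 = background, k >= 1 = object k (26-connected)."""

    labels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def relabeled(self) -> "LabelVolume":
        """Renumber labels to contiguous 1..n preserving order."""
        present = np.unique(self.labels)
        present = present[present > 0]
        lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int32)
        lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
        return LabelVolume(lut[self.labels], self.geometry)


@dataclass
class NucleusRecord:
    """One segmented nucleus in physical coordinates."""

    label: int
    centroid: tuple[float, float, float]        # (x, y, z) um
    volume: float                               # um^3
    voxel_count: int
    mean_intensity: dict[str, float]            # per channel
    distance_to_edge: float                     # um; NaN until spheroid known
    z_slice_span: tuple[int, int]               # (first, last) plane index
    provenance: str                             # "primary" | "secondary"


def smooth(stack: ImageStack, params: SegParams) -> ImageStack:
    """Anisotropy-aware Gaussian smoothing; zero sigma is the identity."""
    g = stack.geometry
    sigma_vox = (
        params.gaussian_sigma_z / g.dz,
        params.gaussian_sigma_xy / g.dy,
        params.gaussian_sigma_xy / g.dx,
    )
    voxels = np.asarray(stack.voxels, dtype=float)
    if all(s == 0 for s in sigma_vox):
        return ImageStack(voxels.copy(), g)
    return ImageStack(ndimage.gaussian_filter(voxels, sigma=sigma_vox, mode="nearest"), g)


def _laplacian(img: np.ndarray, spacings: tuple[float, ...], axes: tuple[int, ...]) -> np.ndarray:
    """Sum of second differences over ``axes``, scaled by 1/spacing^2."""
    out = np.zeros_like(img, dtype=float)
    kernel = np.array([1.0, -2.0, 1.0])
    for ax in axes:
        out += ndimage.correlate1d(img, kernel, axis=ax, mode="nearest") / spacings[ax] ** 2
    return out


def detect_pnvs(smoothed: ImageStack, params: SegParams) -> LabelVolume:
    """Edge-enclosed regions of the smoothed stack: potential nuclear volumes.

    A voxel carries edge evidence when either the per-plane 2D Laplacian
    or the full 3D Laplacian is positive (the bright interior of a nucleus
    is concave-down, so its Laplacian is negative; the surrounding shell is
    positive).  Non-edge regions are labeled with 6-connectivity — the
    topological complement of the 26-connected edge surfaces, so a
    one-voxel edge sheet genuinely separates its two sides; regions
    touching the xy border (ambient background) and speckle below
    ``pnv_min_voxels`` are discarded.

    Edge voxels *interior* to a PNV (seams where nuclei abut, dim
    nucleoli) are deliberately left out of the PNV mask here: they are the
    shape evidence the watershed's distance transform splits clusters on,
    and the watershed stage re-fills them once basins are assigned.

    Multiplying the input by a positive constant scales both Laplacians
    linearly and leaves every sign test, hence the output, unchanged.
    """
    g = smoothed.geometry
    img = np.asarray(smoothed.voxels, dtype=float)
    sp = g.sampling_zyx
    lap3 = _laplacian(img, sp, axes=(0, 1, 2))
    lap2 = _laplacian(img, sp, axes=(1, 2))
    edges = (lap3 > 0) | (lap2 > 0)

    # restrict candidates to above-background voxels; the Otsu split of the
    # smoothed histogram is a relative criterion, so intensity-scale
    # invariance is preserved
    if img.max() > img.min():
        foreground = img > threshold_otsu(img)
    else:
        foreground = np.zeros_like(img, dtype=bool)
    interior = ~edges & foreground
    labels, n = ndimage.label(interior, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return LabelVolume(labels.astype(np.int32), g)

    # discard ambient background: any region touching the xy border
    border = np.zeros_like(interior)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.unique(labels[border & interior])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[touching[touching > 0]] = False
    keep &= counts >= params.pnv_min_voxels
    mask = keep[labels]

    out, _ = ndimage.label(mask, structure=STRUCT_26)
    return LabelVolume(out.astype(np.int32), g)


def _hminima(img: np.ndarray, h: float) -> np.ndarray:
    """Suppress local minima shallower than depth ``h`` (grayscale reconstruction)."""
    return reconstruction(img + h, img, method="erosion")


def split_by_watershed(pnvs: LabelVolume, hmin: float) -> LabelVolume:
    """Distance-transform watershed with H-minima suppression, per PNV.

    Within each PNV independently: the Euclidean distance transform is
    computed in physical um with per-axis voxel spacing on the PNV mask
    *as detected* (internal seam/edge voxels count as boundary, so the
    necks between abutting nuclei show up as distance valleys),
    complemented (negated) so nucleus centres become minima, H-minima
    suppressed at depth ``hmin`` um, and watershed-flooded from the
    surviving minima over the hole-filled PNV — enclosed seam and
    nucleolus voxels are flooded last and divided between the adjacent
    basins, so output objects are solid.  Output labels partition each
    input PNV; no voxel leaves its (filled) PNV and no outside voxel
    gains a label.
    """
    if hmin <= 0:
        raise ValueError("hmin must be > 0")
    g = pnvs.geometry
    labels = pnvs.labels
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    objects = ndimage.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # pad by one voxel so the EDT sees the object boundary
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, labels.shape)
        )
        mask = labels[sl] == idx
        filled = ndimage.binary_fill_holes(mask)
        # never claim voxels of another PNV or already-assigned output
        filled &= mask | ((labels[sl] == 0) & (out[sl] == 0))
        edt = ndimage.distance_transform_edt(mask, sampling=g.sampling_zyx)
        comp = -edt
        suppressed = _hminima(comp, hmin)
        minima = local_minima(suppressed, connectivity=3) & mask
        markers, n_markers = ndimage.label(minima, structure=STRUCT_26)
        if n_markers <= 1:
            out[sl][filled] = next_label
            next_label += 1
            continue
        ws = watershed(suppressed, markers=markers, mask=filled, connectivity=STRUCT_26)
        out[sl][filled] = ws[filled] + (next_label - 1)
        next_label += n_markers
    return LabelVolume(out, g).relabeled()


@dataclass
class _ObjectShape:
    voxel_count: int
    volume: float
    centroid_zyx: tuple[float, float, float]
    axis_ratio: float
    compactness: float
    z_span: tuple[int, int]


def _measure_objects(labels: np.ndarray, geometry: VoxelGeometry) -> dict[int, _ObjectShape]:
    """Physical-space size and shape of every labeled object.

    Principal axes come from the voxel-position covariance in um, with the
    per-voxel box variance (spacing^2/12) added so a one-plane-thick object
    is not scored as degenerate.  Compactness is object volume divided by
    the volume of the inertia-equivalent ellipsoid (semi-axes sqrt(5 *
    eigenvalue)); 1 for a perfect ellipsoid, lower for lumpy clusters.
    """
    g = geometry
    sp = np.array(g.sampling_zyx)
    out: dict[int, _ObjectShape] = {}
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == idx
        coords = np.argwhere(mask).astype(float)
        coords += np.array([s.start for s in sl]) + 0.5
        coords_um = coords * sp
        n = len(coords_um)
        centroid = coords_um.mean(axis=0)
        cov = np.cov(coords_um.T, bias=True) if n > 1 else np.zeros((3, 3))
        cov = np.atleast_2d(cov) + np.diag(sp**2 / 12.0)
        eigvals = np.clip(np.linalg.eigvalsh(cov), 1e-9, None)
        axis_ratio = float(np.sqrt(eigvals[-1] / eigvals[0]))
        semi_axes = np.sqrt(5.0 * eigvals)
        ell_volume = (4.0 / 3.0) * np.pi * np.prod(semi_axes)
        volume = n * g.voxel_volume
        zs = coords[:, 0] - 0.5
        out[idx] = _ObjectShape(
            voxel_count=n,
            volume=volume,
            centroid_zyx=tuple(centroid / sp - 0.5),
            axis_ratio=axis_ratio,
            compactness=float(volume / ell_volume) if ell_volume > 0 else 0.0,
            z_span=(int(zs.min()), int(zs.max())),
        )
    return out


def classify_volumes(
    labels: LabelVolume, params: SegParams
) -> tuple[LabelVolume, LabelVolume]:
    """Sort watershed objects into single nuclei and residual clusters.

    volume in the single-nucleus window AND axis ratio and compactness
    within limits -> single (TNV); too large or mis-shapen -> residual
    cluster (candidate for re-splitting); below the window -> debris,
    discarded.
    """
    lo, hi = params.resolved_volume_range
    shapes = _measure_objects(labels.labels, labels.geometry)
    n_max = int(labels.labels.max())
    fate = np.zeros(n_max + 1, dtype=np.int8)  # 0 debris, 1 single, 2 cluster
    for idx, shape in shapes.items():
        if shape.volume < lo:
            continue  # debris
        is_single = (
            shape.volume <= hi
            and shape.axis_ratio <= params.max_axis_ratio
            and shape.compactness >= params.min_compactness
        )
        fate[idx] = 1 if is_single else 2
    voxel_fate = fate[labels.labels]
    singles = np.where(voxel_fate == 1, labels.labels, 0).astype(np.int32)
    clusters = np.where(voxel_fate == 2, labels.labels, 0).astype(np.int32)
    return (
        LabelVolume(singles, labels.geometry).relabeled(),
        LabelVolume(clusters, labels.geometry).relabeled(),
    )


def _records_from_labels(
    final: LabelVolume,
    well: WellImageSet,
    provenance: dict[int, str],
    origin: tuple[int, int, int],
) -> list[NucleusRecord]:
    g = final.geometry
    labels = final.labels
    shapes = _measure_objects(labels, g)
    index = sorted(shapes)
    records = []
    for idx in index:
        shape = shapes[idx]
        cz, cy, cx = shape.centroid_zyx
        centroid_um = g.centroid_um((cz + origin[0], cy + origin[1], cx + origin[2]))
        means = {}
        for ch, stack in well.channels.items():
            means[ch] = float(
                ndimage.mean(np.asarray(stack.voxels, dtype=float), labels, idx)
            )
        records.append(
            NucleusRecord(
                label=idx,
                centroid=centroid_um,
                volume=shape.volume,
                voxel_count=shape.voxel_count,
                mean_intensity=means,
                distance_to_edge=float("nan"),
                z_slice_span=(shape.z_span[0] + origin[0], shape.z_span[1] + origin[0]),
                provenance=provenance.get(idx, "primary"),
            )
        )
    return records


def segment_nuclei(
    cropped: WellImageSet,
    params: SegParams = SegParams(),
    counterstain: str = "1",
    origin: tuple[int, int, int] = (0, 0, 0),
) -> tuple[LabelVolume, list[NucleusRecord]]:
    """Full two-stage nuclear segmentation of a cropped well.

    smooth -> PNV detection -> primary watershed (hmin_primary) ->
    volume/shape sorting -> secondary watershed of residual clusters
    (hmin_secondary) -> sorting -> merge of primary and secondary TNVs.
    Channel mean intensities in the returned records are measured on the
    RAW (unsmoothed) channels; smoothing is only a detection aid.  The
    parameters are identical across cell types by design.

    ``origin`` is the (z, y, x) index offset of the crop within the
    uncropped stack, so reported centroids live in the uncropped frame.
    """
    stack = cropped.channel(counterstain)
    g = stack.geometry
    smoothed = smooth(stack, params)
    pnvs = detect_pnvs(smoothed, params)
    if pnvs.n_objects == 0:
        empty = LabelVolume(np.zeros_like(pnvs.labels), g)
        return empty, []

    primary = split_by_watershed(pnvs, params.hmin_primary)
    singles, clusters = classify_volumes(primary, params)

    final = singles.labels.copy()
    provenance = {idx: "primary" for idx in range(1, singles.n_objects + 1)}
    next_label = singles.n_objects + 1
    relaxed = dataclasses.replace(
        params, max_axis_ratio=params.max_axis_ratio * params.secondary_axis_ratio_relax
    )
    for _ in range(params.max_secondary_rounds):
        if clusters.n_objects == 0:
            break
        resplit = split_by_watershed(clusters, params.hmin_secondary)
        singles2, clusters = classify_volumes(resplit, relaxed)
        n2 = singles2.n_objects
        if n2:
            offset = next_label - 1
            final = np.where(singles2.labels > 0, singles2.labels + offset, final)
            for idx in range(1, n2 + 1):
                provenance[offset + idx] = "secondary"
            next_label += n2

    final_vol = LabelVolume(final, g).relabeled()
    # relabeling preserves order, so provenance indices map 1:1
    ordered = [provenance[idx] for idx in sorted(provenance) if idx <= final.max()]
    prov_map = {i + 1: p for i, p in enumerate(ordered)}
    records = _records_from_labels(final_vol, cropped, prov_map, origin)
    return final_vol, records


def write_label_tiff(volume: LabelVolume, path) -> None:
    """Export a label volume as a multi-plane TIFF for visual QC."""
    import tifffile

    tifffile.imwrite(path, volume.labels.astype(np.uint16))
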