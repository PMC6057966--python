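"""Ground-truth-annotated synthetic spheroid z-stacks.

Emulates the inputs of the cleared-spheroid assay: a Hoechst-like
counterstain channel of ellipsoidal nuclei packed inside a spherical
aggregate, an optional second channel marking a seeded fraction of nuclei
(a Cell-Tracker-style mixing experiment), depth-dependent signal
attenuation and blur standing in for residual light scattering in poorly
cleared samples, and additive/shot sensor noise.  Every stack is fully
reproducible from its seed and ships with the exact centroids, ellipsoid
axes and label flags used to render it.

The generator is deliberately geometric rather than optical: no PSF model,
no refractive-index simulation.  Its job is to produce stacks whose
difficulty (touching nuclei, 5 um z-sampling, intensity variation, depth
degradation) exercises the same failure modes as real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .geometry import DEFAULT_GEOMETRY, VoxelGeometry
from .stack_io import ImageStack, WellImageSet

#: Channel names used in synthetic wells and their plate file names.
CHANNEL_NUCLEI = "1"
CHANNEL_LABEL = "2"

TRUTH_COLUMNS = ["x_um", "y_um", "z_um", "labeled", "semi_axis_a_um",
                 "semi_axis_b_um", "semi_axis_c_um"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic spheroid.

    Defaults describe a 3-days-in-vitro 250-cell T47D-like spheroid:
    ~250 nuclei of mean diameter 11.6 um (SD 2.2 um) packed in a 50 um
    radius aggregate, imaged at 0.64 um xy / 5 um z.  ``attenuation_coeff``
    and ``depth_blur_gain`` are both zero by default (a well-cleared
    sample); raising them emulates an uncleared one.
    """

    n_nuclei: int = 250
    spheroid_radius: float = 50.0
    nucleus_diameter_mean: float = 11.6
    nucleus_diameter_sd: float = 2.2
    labeled_fraction: float = 0.0
    attenuation_coeff: float = 0.0      # per um of depth
    depth_blur_gain: float = 0.0        # added blur sigma (um) per um of depth
    gaussian_noise_sd: float = 50.0     # counts
    poisson_noise: bool = False
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    seed: int = 0
    # rendering details
    min_separation: float | None = None  # um; None -> 0.7 x mean diameter
    margin_xy: float = 20.0              # um of empty border around the spheroid
    margin_z_planes: int = 2             # empty planes above and below
    nuclear_intensity: float = 3000.0    # mean interior counts before blur
    intensity_cv: float = 0.25           # per-nucleus lognormal variation
    axis_ratio_sd: float = 0.12          # lognormal sd of per-axis eccentricity
    nucleolus_contrast: float = 0.3      # dim interior spot; 0 disables
    nucleolus_radius_frac: float = 0.35
    seam_contrast: float = 0.8           # junction dimming between abutting nuclei
    seam_width_q: float = 0.35           # seam half-width, ellipsoid-q units
    base_blur_sigma_xy: float = 0.8      # um, optics stand-in
    base_blur_sigma_z: float = 1.5       # um
    background_offset: float = 100.0
    label_intensity: float = 2500.0      # second-channel interior counts
    render_label_channel: bool | None = None  # None: only when fraction > 0;
                                              # True forces a (possibly dark)
                                              # label channel, as for the 0%
                                              # wells of a titration plate

    def __post_init__(self) -> None:
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if self.attenuation_coeff < 0 or self.depth_blur_gain < 0:
            raise ValueError("degradation coefficients must be >= 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")

    @property
    def resolved_min_separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 0.7 * self.nucleus_diameter_mean


@dataclass
class GroundTruth:
    """Exact rendering parameters of every nucleus in a synthetic stack."""

    centroids: np.ndarray          # (n, 3) um, columns x, y, z
    labels: np.ndarray             # (n,) bool, tracker-positive
    nucleus_axes: np.ndarray       # (n, 3) um, semi-axes a >= b >= c

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=bool).reshape(-1)
        self.nucleus_axes = np.asarray(self.nucleus_axes, dtype=float).reshape(-1, 3)
        if not (len(self.centroids) == len(self.labels) == len(self.nucleus_axes)):
            raise ValueError("ground-truth arrays must have equal length")

    def __len__(self) -> int:
        return len(self.centroids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.centroids[:, 0],
                "y_um": self.centroids[:, 1],
                "z_um": self.centroids[:, 2],
                "labeled": self.labels.astype(int),
                "semi_axis_a_um": self.nucleus_axes[:, 0],
                "semi_axis_b_um": self.nucleus_axes[:, 1],
                "semi_axis_c_um": self.nucleus_axes[:, 2],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            centroids=df[["x_um", "y_um", "z_um"]].to_numpy(float),
            labels=df["labeled"].to_numpy() > 0,
            nucleus_axes=df[
                ["semi_axis_a_um", "semi_axis_b_um", "semi_axis_c_um"]
            ].to_numpy(float),
        )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (quaternion construction)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _place_centroids(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centres inside the spheroid.

    Centres stay ``mean radius`` inside the aggregate surface so rendered
    nuclei remain within the spheroid; pairwise separation is enforced at
    ``spec.resolved_min_separation`` (default 0.7 x mean diameter, which
    still allows realistic touching clusters).
    """
    n = spec.n_nuclei
    if n == 0:
        return np.zeros((0, 3))
    r_place = max(spec.spheroid_radius - 0.5 * spec.nucleus_diameter_mean, 1.0)
    min_sep = spec.resolved_min_separation
    placed: list[np.ndarray] = []
    max_attempts = 2000 * n
    attempts = 0
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        p = rng.uniform(-r_place, r_place, size=3)
        if p @ p > r_place * r_place:
            continue
        if placed:
            d2 = np.sum((np.asarray(placed) - p) ** 2, axis=1)
            if d2.min() < min_sep * min_sep:
                continue
        placed.append(p)
    if len(placed) < n:
        raise RuntimeError(
            f"could only place {len(placed)} of {n} nuclei at minimum "
            f"separation {min_sep:.2f} um in a {spec.spheroid_radius:.0f} um "
            "radius spheroid; reduce n_nuclei or the separation"
        )
    return np.asarray(placed)


def _sample_axes(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-nucleus ellipsoid semi-axes (um), geometric-mean diameter ~ N(mean, sd)."""
    diam = rng.normal(spec.nucleus_diameter_mean, spec.nucleus_diameter_sd, size=n)
    diam = np.clip(diam, 4.0, None)
    ecc = np.exp(rng.normal(0.0, spec.axis_ratio_sd, size=(n, 3)))
    ecc /= np.prod(ecc, axis=1, keepdims=True) ** (1.0 / 3.0)  # keep volume
    axes = 0.5 * diam[:, None] * ecc
    return -np.sort(-axes, axis=1)  # a >= b >= c


def _ellipsoid_box(
    center_um: np.ndarray,
    axes_um: np.ndarray,
    geometry: VoxelGeometry,
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray] | None:
    """Voxel bounding box (lo, hi) of an ellipsoid, clipped to the stack."""
    spacing = np.array(geometry.sampling_zyx)  # (dz, dy, dx)
    center_zyx = center_um[::-1]
    half = float(axes_um.max())
    lo = np.maximum(((center_zyx - half) / spacing - 0.5).astype(int), 0)
    hi = np.minimum(((center_zyx + half) / spacing + 1.5).astype(int), np.array(shape))
    if np.any(lo >= hi):
        return None
    return lo, hi


def _ellipsoid_q(
    center_um: np.ndarray,
    axes_um: np.ndarray,
    rotation: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    geometry: VoxelGeometry,
) -> np.ndarray:
    """Quadratic form q(p) over a voxel box; q <= 1 is the ellipsoid interior."""
    spacing = np.array(geometry.sampling_zyx)
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) + 0.5) * spacing[0],
        (np.arange(lo[1], hi[1]) + 0.5) * spacing[1],
        (np.arange(lo[2], hi[2]) + 0.5) * spacing[2],
        indexing="ij",
    )
    rel = np.stack([xx - center_um[0], yy - center_um[1], zz - center_um[2]], axis=-1)
    local = rel @ rotation  # into the ellipsoid's principal frame
    return np.sum((local / axes_um) ** 2, axis=-1)


def _render_nuclei(
    spec: SyntheticSpec,
    shape: tuple[int, int, int],
    centroids: np.ndarray,
    axes: np.ndarray,
    rotations: list[np.ndarray],
    intensities: np.ndarray,
    labels: np.ndarray,
    nucleolus_offsets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Paint all nuclei as a winner-take-all partition with dim seams.

    Nuclei in tissue abut but do not interpenetrate: each voxel claimed by
    more than one sampled ellipsoid goes to the nearest one (smallest
    quadratic form), and intensity is dimmed where the two best claims are
    close — a thin dark seam standing in for the nuclear envelopes and
    cytoplasm between touching nuclei.  Without this seam touching nuclei
    would have no intensity boundary and no segmentation method could
    separate them.
    """
    g = spec.geometry
    best_q = np.full(shape, np.inf, dtype=np.float32)
    second_q = np.full(shape, np.inf, dtype=np.float32)
    winner = np.zeros(shape, dtype=np.int32)
    boxes: list[tuple[np.ndarray, np.ndarray] | None] = []
    for i in range(len(centroids)):
        box = _ellipsoid_box(centroids[i], axes[i], g, shape)
        boxes.append(box)
        if box is None:
            continue
        lo, hi = box
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        q = _ellipsoid_q(centroids[i], axes[i], rotations[i], lo, hi, g).astype(np.float32)
        bq, sq, wn = best_q[sl], second_q[sl], winner[sl]
        better = q < bq
        second_q[sl] = np.where(better, bq, np.minimum(sq, q))
        best_q[sl] = np.where(better, q, bq)
        winner[sl] = np.where(better, i + 1, wn)

    inside = best_q <= 1.0
    with np.errstate(invalid="ignore"):
        gap = (second_q - best_q) / max(spec.seam_width_q, 1e-9)
    seam = np.where(np.isfinite(gap),
                    np.clip(gap, 1.0 - spec.seam_contrast, 1.0), 1.0)
    intensity_lut = np.concatenate([[0.0], intensities]).astype(np.float32)
    nuc = np.where(inside, intensity_lut[winner] * seam, 0.0).astype(np.float32)

    if spec.nucleolus_contrast > 0:
        for i, box in enumerate(boxes):
            if box is None:
                continue
            lo, hi = box
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            qn = _ellipsoid_q(
                centroids[i] + nucleolus_offsets[i] * axes[i],
                axes[i] * spec.nucleolus_radius_frac,
                rotations[i], lo, hi, g,
            )
            m = (winner[sl] == i + 1) & inside[sl] & (qn <= 1.0)
            nuc[sl][m] *= 1.0 - spec.nucleolus_contrast

    lab = None
    render_label = (spec.render_label_channel if spec.render_label_channel
                    is not None else spec.labeled_fraction > 0)
    if render_label:
        label_lut = np.concatenate([[False], labels])
        lab = np.where(inside & label_lut[winner],
                       np.float32(spec.label_intensity), np.float32(0.0))
    return nuc, lab


def degrade_for_clearing(
    stack: ImageStack,
    attenuation_coeff: float,
    depth_blur_gain: float,
) -> ImageStack:
    """Apply depth-dependent signal loss and blur to a stack.

    The plane at depth ``d = z_index * dz`` um is scaled by
    ``exp(-attenuation_coeff * d)`` and blurred in-plane with a Gaussian of
    sigma ``depth_blur_gain * d`` um.  With both coefficients zero the
    output equals the input voxelwise.
    """
    if attenuation_coeff < 0 or depth_blur_gain < 0:
        raise ValueError("degradation coefficients must be >= 0")
    if attenuation_coeff == 0 and depth_blur_gain == 0:
        return ImageStack(stack.voxels.copy(), stack.geometry)
    g = stack.geometry
    out = np.asarray(stack.voxels, dtype=float).copy()
    for zi in range(out.shape[0]):
        depth = zi * g.dz
        plane = out[zi]
        if depth_blur_gain > 0 and depth > 0:
            sigma_px = depth_blur_gain * depth / np.array([g.dy, g.dx])
            plane = ndimage.gaussian_filter(plane, sigma=sigma_px, mode="constant")
        out[zi] = plane * np.exp(-attenuation_coeff * depth)
    if np.issubdtype(stack.voxels.dtype, np.integer):
        out = np.clip(np.rint(out), 0, np.iinfo(stack.voxels.dtype).max)
        out = out.astype(stack.voxels.dtype)
    return ImageStack(out, g)


def _finalize_channel(
    canvas: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Optics blur -> depth degradation -> background -> noise -> uint16."""
    g = spec.geometry
    sigma_vox = (
        spec.base_blur_sigma_z / g.dz,
        spec.base_blur_sigma_xy / g.dy,
        spec.base_blur_sigma_xy / g.dx,
    )
    out = ndimage.gaussian_filter(canvas, sigma=sigma_vox, mode="constant")
    if spec.attenuation_coeff > 0 or spec.depth_blur_gain > 0:
        out = degrade_for_clearing(
            ImageStack(out, g), spec.attenuation_coeff, spec.depth_blur_gain
        ).voxels
    out = out + spec.background_offset
    if spec.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if spec.gaussian_noise_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_noise_sd, size=out.shape)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def generate_spheroid(
    spec: SyntheticSpec,
    plate_id: str = "synthetic",
    well_id: str = "A01",
) -> tuple[WellImageSet, GroundTruth]:
    """Render one synthetic spheroid well.

    Returns the multi-channel :class:`WellImageSet` (counterstain channel
    always; label channel only when ``labeled_fraction > 0``) and the
    :class:`GroundTruth` used to render it.  Identical spec (including
    seed) gives identical output.
    """
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)

    extent_xy = 2.0 * (spec.spheroid_radius + spec.margin_xy)
    nx = int(np.ceil(extent_xy / g.dx))
    ny = int(np.ceil(extent_xy / g.dy))
    nz = int(np.ceil(2.0 * spec.spheroid_radius / g.dz)) + 2 * spec.margin_z_planes
    nz = max(nz, 2)
    center = np.array(
        [(nx * g.dx) / 2.0, (ny * g.dy) / 2.0, (nz * g.dz) / 2.0]
    )  # um, (x, y, z)

    rel = _place_centroids(spec, rng)
    centroids = rel + center
    axes = _sample_axes(spec, rng, len(centroids))
    labels = rng.random(len(centroids)) < spec.labeled_fraction
    intensities = spec.nuclear_intensity * np.exp(
        rng.normal(0.0, spec.intensity_cv, size=len(centroids))
    )
    rotations = [_random_rotation(rng) for _ in range(len(centroids))]
    nucleolus_offsets = rng.uniform(-0.3, 0.3, size=(len(centroids), 3))

    nuc, lab = _render_nuclei(
        spec, (nz, ny, nx), centroids, axes, rotations,
        intensities, labels, nucleolus_offsets,
    )

    channels = {CHANNEL_NUCLEI: ImageStack(_finalize_channel(nuc, spec, rng), g)}
    if lab is not None:
        channels[CHANNEL_LABEL] = ImageStack(_finalize_channel(lab, spec, rng), g)

    truth = GroundTruth(centroids=centroids, labels=labels, nucleus_axes=axes)
    well = WellImageSet(plate_id=plate_id, well_id=well_id,
                        channels=channels, geometry=g)
    return well, truth


def _well_row_col(well_id: str) -> tuple[int, int]:
    m = __import__("re").match(r"^([A-Pa-p])(\d{1,2})$", well_id)
    if not m:
        raise ValueError(f"well id {well_id!r} not of the form letter+number (e.g. B02)")
    return ord(m.group(1).upper()) - ord("A") + 1, int(m.group(2))


def plane_filename(well_id: str, channel: str, plane: int) -> str:
    """File name for one plane in the plate layout stack_io discovers."""
    row, col = _well_row_col(well_id)
    return f"r{row:02d}c{col:02d}f01p{plane:02d}-ch{channel}sk1fk1fl1.tiff"


def truth_sidecar_path(plate_dir: str | Path, well_id: str) -> Path:
    return Path(plate_dir) / f"{well_id}_truth.csv"


def write_well_tiffs(well: WellImageSet, plate_dir: str | Path) -> list[Path]:
    """Write one well as single-plane 16-bit TIFFs (planes numbered from 1)."""
    plate_dir = Path(plate_dir)
    plate_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for channel, stack in well.channels.items():
        for zi in range(stack.shape[0]):
            path = plate_dir / plane_filename(well.well_id, channel, zi + 1)
            tifffile.imwrite(path, stack.voxels[zi].astype(np.uint16))
            written.append(path)
    return written


def generate_plate(
    specs: Mapping[str, SyntheticSpec],
    out_dir: str | Path,
    plate_id: str = "synthetic",
) -> dict[str, list[Path]]:
    """Render a plate of synthetic wells into a folder of TIFF planes.

    One ground-truth sidecar CSV is written per well next to the TIFFs.
    The layout is exactly what ``stack_io.discover_wells`` consumes with
    the default filename pattern.  Returns written paths per well.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen = set()
    for well_id in specs:
        key = well_id.upper()
        if key in seen:
            raise ValueError(f"duplicate well id {well_id!r}")
        seen.add(key)
        _well_row_col(well_id)  # validate early, before any file is written
    written: dict[str, list[Path]] = {}
    for well_id in sorted(specs):
        well, truth = generate_spheroid(specs[well_id], plate_id=plate_id,
                                        well_id=well_id)
        paths = write_well_tiffs(well, out_dir)
        sidecar = truth_sidecar_path(out_dir, well_id)
        truth.save(sidecar)
        written[well_id] = paths + [sidecar]
    return written


def spec_variant(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    """Convenience wrapper around dataclasses.replace for spec sweeps."""
    return replace(spec, **overrides)
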