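"""Decide whether a well holds an analyzable spheroid and crop to it.

A rough above-background mask is closed morphologically, the largest
connected component is taken as the candidate spheroid, and the well is
accepted only if that component is large enough and does not overlap the
xy edge of the field (a spheroid cut off laterally cannot be analyzed;
truncation in z is tolerated, since tall spheroids routinely extend past
the imageable depth).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack_io import ImageStack, WellImageSet


class GateReason(str, Enum):
    OK = "ok"
    NO_SPHEROID = "no_spheroid"
    TOUCHES_XY_EDGE = "touches_xy_edge"


@dataclass
class GateResult:
    accepted: bool
    reason: GateReason
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None
    rough_mask: np.ndarray | None


@dataclass(frozen=True)
class GateParams:
    """Spheroid-presence gate configuration.

    threshold_policy : "otsu" (full-stack histogram), "fixed", "percentile"
    closing_radii_um : structuring-element radii (z, y, x) in um
    min_volume_um3   : smallest accepted component; default the volume of a
                       50 um diameter sphere (~6.5e4 um^3), far below even a
                       250-cell spheroid but above debris
    margin_um        : bounding-box dilation before cropping
    """

    threshold_policy: str = "otsu"
    threshold_value: float | None = None
    threshold_percentile: float = 99.0
    closing_radii_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    min_volume_um3: float = (4.0 / 3.0) * np.pi * 25.0**3
    margin_um: float = 10.0
    min_contrast_ratio: float = 3.0      # above/below-threshold mean intensity;
                                         # bisected noise gives ~2, a real spheroid
                                         # 10+; below this the mask is empty


def _resolve_threshold(voxels: np.ndarray, params: GateParams) -> float:
    if params.threshold_policy == "fixed":
        if params.threshold_value is None:
            raise ValueError("fixed threshold policy requires threshold_value")
        return float(params.threshold_value)
    if params.threshold_policy == "percentile":
        return float(np.percentile(voxels, params.threshold_percentile))
    if params.threshold_policy == "otsu":
        return float(threshold_otsu(voxels))
    raise ValueError(f"unknown threshold policy {params.threshold_policy!r}")


def _ellipsoid_selem(radii_vox: tuple[float, float, float]) -> np.ndarray:
    """Anisotropy-aware ellipsoidal structuring element (odd-sized)."""
    r = [max(int(np.floor(v)), 0) for v in radii_vox]
    zz, yy, xx = np.ogrid[-r[0]:r[0] + 1, -r[1]:r[1] + 1, -r[2]:r[2] + 1]
    denom = [max(v, 1e-9) for v in radii_vox]
    return (zz / denom[0]) ** 2 + (yy / denom[1]) ** 2 + (xx / denom[2]) ** 2 <= 1.0


def rough_spheroid_mask(
    nuclear_stack: ImageStack, params: GateParams = GateParams()
) -> np.ndarray:
    """Above-background voxels, morphologically closed into a solid blob.

    An all-constant stack (nothing imaged) yields an empty mask rather
    than an error.
    """
    voxels = np.asarray(nuclear_stack.voxels)
    if voxels.max() == voxels.min():
        return np.zeros(voxels.shape, dtype=bool)
    thr = _resolve_threshold(voxels, params)
    bright = voxels > thr
    if not bright.any() or bright.all():
        return np.zeros(voxels.shape, dtype=bool)
    # on a signal-free stack any threshold just bisects the noise; demand
    # real contrast between the two sides before building a mask
    above = float(voxels[bright].mean())
    below = float(voxels[~bright].mean())
    if above < params.min_contrast_ratio * max(below, 1e-9):
        return np.zeros(voxels.shape, dtype=bool)
    g = nuclear_stack.geometry
    radii_vox = (
        params.closing_radii_um[0] / g.dz,
        params.closing_radii_um[1] / g.dy,
        params.closing_radii_um[2] / g.dx,
    )
    selem = _ellipsoid_selem(radii_vox)
    # pad so the closing is border-neutral (scipy erodes at borders otherwise)
    pad = tuple((s // 2, s // 2) for s in selem.shape)
    padded = np.pad(bright, pad, mode="edge")
    closed = ndimage.binary_closing(padded, structure=selem)
    sl = tuple(slice(p[0], dim + p[0]) for p, dim in zip(pad, bright.shape))
    return ndimage.binary_fill_holes(closed[sl])


def gate_and_crop(
    well: WellImageSet,
    rough_mask: np.ndarray,
    params: GateParams = GateParams(),
) -> tuple[GateResult, WellImageSet | None]:
    """Accept/reject the well and crop all channels to the spheroid bbox.

    The largest 26-connected component of ``rough_mask`` is the candidate.
    Accepted iff its volume is at least ``min_volume_um3`` and its xy
    extent stays off the first/last row and column.  The bounding box is
    dilated by ``margin_um`` (clipped to the stack); rejections are
    results, not errors.
    """
    g = well.geometry
    labels, n = ndimage.label(rough_mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return GateResult(False, GateReason.NO_SPHEROID, None, rough_mask), None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    component = labels == biggest
    volume = counts[biggest] * g.voxel_volume
    if volume < params.min_volume_um3:
        return GateResult(False, GateReason.NO_SPHEROID, None, rough_mask), None

    nz, ny, nx = component.shape
    zs, ys, xs = np.nonzero(component)
    if ys.min() == 0 or ys.max() == ny - 1 or xs.min() == 0 or xs.max() == nx - 1:
        return GateResult(False, GateReason.TOUCHES_XY_EDGE, None, rough_mask), None

    mz = max(int(round(params.margin_um / g.dz)), 0)
    my = max(int(round(params.margin_um / g.dy)), 0)
    mx = max(int(round(params.margin_um / g.dx)), 0)
    bbox = (
        (max(zs.min() - mz, 0), min(zs.max() + 1 + mz, nz)),
        (max(ys.min() - my, 0), min(ys.max() + 1 + my, ny)),
        (max(xs.min() - mx, 0), min(xs.max() + 1 + mx, nx)),
    )
    sl = tuple(slice(a, b) for a, b in bbox)
    cropped = WellImageSet(
        plate_id=well.plate_id,
        well_id=well.well_id,
        channels={
            ch: ImageStack(stack.voxels[sl].copy(), g)
            for ch, stack in well.channels.items()
        },
        geometry=g,
    )
    return GateResult(True, GateReason.OK, bbox, rough_mask), cropped
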