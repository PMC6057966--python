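"""Post-segmentation metrics: clearing quality, cutoff cropping, labeling.

The central idea: in a solid spheroid the per-slice ratio of segmented
nuclear area to whole-spheroid slice area should stay roughly constant
with depth; where clearing or signal fails, segmentation thins out and the
ratio collapses.  The plane where the smoothed ratio first drops 50% from
its maximum is the *nuclear segmentation cutoff* — the depth beyond which
nuclei are no longer reliably segmented.  Dividing that depth by the
*approximate spheroid height* (twice the depth of the widest slice) gives
the clearing metric, a (0, 1] summary of how much of the spheroid was
successfully analyzed.

Plane depth convention: plane k counted 1-based from the shallowest imaged
plane lies at depth k * dz um.  Height and cutoff share it, so the
clearing metric is a pure ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .nuclei import LabelVolume, NucleusRecord
from .spheroid import SpheroidVolume, sample_edge_distance

DEPTH_BIN_EDGES_UM = (60.0, 120.0)   # bottom < 60 <= middle <= 120 < top
OUTER_LAYER_UM = 12.8                # within this of the edge -> outer layer


class CutoffRule(str, Enum):
    FIFTY_PERCENT = "fifty_percent"
    TEN_PERCENT_AREA_FALLBACK = "ten_percent_area_fallback"
    NONE = "none"


@dataclass
class CutoffResult:
    ratio_per_slice: np.ndarray        # NaN on planes with zero spheroid area
    smoothed_ratio: np.ndarray
    cutoff_slice: int | None           # 1-based plane index
    cutoff_rule_used: CutoffRule

    def cutoff_depth_um(self, dz: float) -> float | None:
        if self.cutoff_slice is None:
            return None
        return self.cutoff_slice * dz


@dataclass
class ClearingSummary:
    approximate_height: float | None
    cutoff_depth: float | None
    clearing_metric: float | None
    excluded_over_one: bool


@dataclass
class RegionBins:
    depth_bin: list[str]   # per nucleus: bottom | middle | top
    layer_bin: list[str]   # per nucleus: outer | inner


def approximate_height(
    slice_area: np.ndarray, dz: float, decay_fraction: float = 0.97
) -> float | None:
    """Twice the depth of the widest slice, or None if the midpoint was missed.

    The widest plane k (1-based) gives height 2 * k * dz.  If no plane
    *after* the maximum falls below ``decay_fraction`` of the maximum the
    spheroid midpoint was evidently not imaged and the height is undefined
    (decay on the near side is irrelevant).
    """
    areas = np.asarray(slice_area, dtype=float)
    if areas.size == 0 or areas.max() <= 0:
        return None
    k0 = int(np.argmax(areas))  # 0-based
    after = areas[k0 + 1:]
    if after.size == 0 or not np.any(after < decay_fraction * areas[k0]):
        return None
    return 2.0 * (k0 + 1) * dz


def nuclear_segmentation_cutoff(
    nuclei: LabelVolume,
    spheroid: SpheroidVolume,
    smoothing_window: int = 3,
    min_area_fraction: float = 0.10,
) -> CutoffResult:
    """Find the plane where per-slice segmentation coverage collapses.

    Per plane, ratio = segmented-nuclei area / spheroid slice area; the
    ratio is smoothed with a centered moving average (odd window).  The
    cutoff is the first plane after the smoothed maximum where the
    smoothed ratio drops below 50% of that maximum.  If that never
    happens, the fallback is the first plane after the spheroid
    slice-area maximum where the slice area drops below 10% of its
    maximum.  If neither fires the cutoff is undefined and the full stack
    is kept.

    Planes whose spheroid area is below ``min_area_fraction`` of the
    maximum slice area are excluded from the ratio: near the spheroid
    poles the mask is a sliver defined by the very nuclei in the
    numerator, so the quotient is ill-conditioned there (it pins at ~1 and
    would fake a 50% collapse mid-spheroid).  The default matches the
    scale of the 10%-area fallback rule.
    """
    if smoothing_window % 2 == 0 or smoothing_window < 1:
        raise ValueError("smoothing_window must be odd and >= 1")
    g = nuclei.geometry
    nuc_area = (nuclei.labels > 0).sum(axis=(1, 2)) * g.pixel_area
    sph_area = np.asarray(spheroid.slice_area, dtype=float)
    min_area = min_area_fraction * (sph_area.max() if sph_area.size else 0.0)
    valid_plane = sph_area > max(min_area, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid_plane, nuc_area / np.where(valid_plane, sph_area, 1.0), np.nan)

    smoothed = _nan_moving_average(ratio, smoothing_window)

    cutoff: int | None = None
    rule = CutoffRule.NONE
    valid = np.isfinite(smoothed)
    if valid.any() and np.nanmax(smoothed) > 0:
        kmax = int(np.nanargmax(smoothed))
        half = 0.5 * smoothed[kmax]
        for k in range(kmax + 1, len(smoothed)):
            if valid[k] and smoothed[k] < half:
                cutoff = k + 1  # 1-based
                rule = CutoffRule.FIFTY_PERCENT
                break
    if cutoff is None and sph_area.size and sph_area.max() > 0:
        amax = int(np.argmax(sph_area))
        for k in range(amax + 1, len(sph_area)):
            if sph_area[k] < 0.10 * sph_area[amax]:
                cutoff = k + 1
                rule = CutoffRule.TEN_PERCENT_AREA_FALLBACK
                break
    return CutoffResult(ratio_per_slice=ratio, smoothed_ratio=smoothed,
                        cutoff_slice=cutoff, cutoff_rule_used=rule)


def _nan_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs (edges use the available span)."""
    half = window // 2
    out = np.full_like(values, np.nan, dtype=float)
    for i in range(len(values)):
        seg = values[max(i - half, 0):i + half + 1]
        good = np.isfinite(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


def clearing_metric(
    cutoff: CutoffResult, height_um: float | None, dz: float
) -> ClearingSummary:
    """Cutoff depth over approximate height, with the >1 exclusion rule.

    The cutoff depth is reported even when the height (and so the metric)
    is undefined.  A metric over 1 signals a mis-approximated height; the
    spheroid is flagged and the metric withheld from aggregation.
    """
    cutoff_depth = cutoff.cutoff_depth_um(dz)
    if cutoff_depth is None or height_um is None:
        return ClearingSummary(height_um, cutoff_depth, None, False)
    metric = cutoff_depth / height_um
    if metric > 1.0:
        return ClearingSummary(height_um, cutoff_depth, None, True)
    return ClearingSummary(height_um, cutoff_depth, metric, False)


def apply_cutoff(
    records: list[NucleusRecord], cutoff: CutoffResult, dz: float
) -> list[NucleusRecord]:
    """Keep only nuclei segmented shallower than the cutoff depth.

    A nucleus is retained iff its centroid z-depth is strictly below the
    cutoff depth; an undefined cutoff retains everything.
    """
    depth = cutoff.cutoff_depth_um(dz)
    if depth is None:
        return list(records)
    return [r for r in records if r.centroid[2] < depth]


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the positive/negative intensity threshold is resolved.

    mode "fixed": use ``value``.  mode "plate_control": pool the nucleus
    mean intensities of designated 100%-labeled control wells, take a
    lower-tail percentile (default the 1st) and scale it by
    ``control_margin``.  The margin (default 0.5) accounts for labeled
    cells in mixed spheroids being systematically dimmer than in pure
    positive controls — in a 100% control every nuclear ROI also collects
    blur/scatter spill-over from labeled neighbours, a boost absent once
    labeled cells are diluted among unlabeled ones.
    """

    mode: str = "plate_control"
    value: float | None = None
    lower_tail_percentile: float = 1.0
    control_margin: float = 0.5

    def resolve(self, control_intensities: np.ndarray | None = None) -> float:
        if self.mode == "fixed":
            if self.value is None:
                raise ValueError("fixed threshold policy requires a value")
            return float(self.value)
        if self.mode == "plate_control":
            if control_intensities is None or len(control_intensities) == 0:
                raise ValueError(
                    "plate_control threshold policy requires nucleus intensities "
                    "from designated positive-control wells"
                )
            tail = float(np.percentile(control_intensities, self.lower_tail_percentile))
            return self.control_margin * tail
        raise ValueError(f"unknown threshold mode {self.mode!r}")


def classify_positive(
    records: list[NucleusRecord],
    channel: str,
    threshold: float,
) -> tuple[list[bool], float]:
    """Flag label-positive nuclei (mean intensity >= threshold) and the fraction.

    Returns per-record flags and positives / total over the given
    (cutoff-filtered) records; an empty record list gives fraction 0.
    """
    flags = [r.mean_intensity[channel] >= threshold for r in records]
    fraction = (sum(flags) / len(flags)) if flags else 0.0
    return flags, fraction


def bin_regions(
    records: list[NucleusRecord],
    spheroid: SpheroidVolume,
) -> RegionBins:
    """Assign each nucleus a depth bin and an outer/inner layer bin.

    Depth: bottom < 60 um <= middle <= 120 um < top, from the centroid
    z-depth.  Layer: outer iff the spheroid edge distance sampled at the
    centroid is within 12.8 um (inclusive); a centroid outside the mask
    reads distance 0 and is outer.
    """
    depth_bin = []
    layer_bin = []
    lo, hi = DEPTH_BIN_EDGES_UM
    for r in records:
        z = r.centroid[2]
        if z < lo:
            depth_bin.append("bottom")
        elif z <= hi:
            depth_bin.append("middle")
        else:
            depth_bin.append("top")
        d = r.distance_to_edge
        if not np.isfinite(d):
            d = sample_edge_distance(spheroid, r.centroid)
        layer_bin.append("outer" if d <= OUTER_LAYER_UM else "inner")
    return RegionBins(depth_bin=depth_bin, layer_bin=layer_bin)
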