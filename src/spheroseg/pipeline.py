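"""Per-well analysis pipeline: load -> gate -> segment -> spheroid -> metrics.

This module glues the stages together for one well and produces the
per-spheroid outputs (nucleus table + metadata document) and the summary
row that the plate-level aggregation consumes.  It contains no randomness:
identical inputs and configuration give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .benchmark import centroids_of_records
from .gate import GateParams, GateReason, gate_and_crop, rough_spheroid_mask
from .geometry import VoxelGeometry
from .nuclei import LabelVolume, NucleusRecord, SegParams, segment_nuclei
from .postseg import (
    CutoffResult,
    ThresholdPolicy,
    apply_cutoff,
    approximate_height,
    bin_regions,
    classify_positive,
    clearing_metric,
    nuclear_segmentation_cutoff,
)
from .spheroid import SpheroidSegParams, SpheroidVolume, sample_edge_distance, whole_spheroid
from .stack_io import WellImageSet, write_spheroid_output


@dataclass(frozen=True)
class PipelineParams:
    """Everything one well needs, minus the threshold (resolved per plate)."""

    counterstain: str = "1"
    label_channels: tuple[str, ...] = ()
    gate: GateParams = field(default_factory=GateParams)
    seg: SegParams = field(default_factory=SegParams)
    spheroid: SpheroidSegParams = field(default_factory=SpheroidSegParams)
    cutoff_smoothing_window: int = 3
    height_decay_fraction: float = 0.97


@dataclass
class WellAnalysis:
    """Everything computed for one accepted well."""

    well_id: str
    gate_reason: GateReason
    records: list[NucleusRecord]              # all segmented nuclei
    retained: list[NucleusRecord]             # after cutoff filtering
    labels: LabelVolume | None
    spheroid: SpheroidVolume | None
    cutoff: CutoffResult | None
    height_um: float | None
    clearing: dict | None
    bbox: tuple | None

    @property
    def accepted(self) -> bool:
        return self.gate_reason == GateReason.OK


def analyze_well(
    well: WellImageSet, params: PipelineParams = PipelineParams()
) -> WellAnalysis:
    """Run the full single-well analysis (no label thresholding yet)."""
    if params.counterstain not in well.channels:
        raise KeyError(
            f"well {well.well_id}: counterstain channel {params.counterstain!r} missing"
        )
    g = well.geometry
    nuclear = well.channel(params.counterstain)
    rough = rough_spheroid_mask(nuclear, params.gate)
    gate_result, cropped = gate_and_crop(well, rough, params.gate)
    if not gate_result.accepted:
        return WellAnalysis(well.well_id, gate_result.reason, [], [], None, None,
                            None, None, None, None)

    origin = tuple(b[0] for b in gate_result.bbox)
    labels, records = segment_nuclei(
        cropped, params.seg, counterstain=params.counterstain, origin=origin
    )
    spheroid = whole_spheroid(
        cropped.channel(params.counterstain), labels, params.spheroid
    )
    # lift spheroid geometry into the uncropped frame for depth/area series
    slice_area_full = np.zeros(nuclear.shape[0])
    z0 = origin[0]
    slice_area_full[z0:z0 + len(spheroid.slice_area)] = spheroid.slice_area

    crop_offset_um = (origin[2] * g.dx, origin[1] * g.dy, origin[0] * g.dz)
    for r in records:
        local = (r.centroid[0] - crop_offset_um[0],
                 r.centroid[1] - crop_offset_um[1],
                 r.centroid[2] - crop_offset_um[2])
        r.distance_to_edge = sample_edge_distance(spheroid, local)

    nuc_full = LabelVolume(labels.labels, g)
    sph_full = SpheroidVolume(
        mask=spheroid.mask, slice_area=slice_area_full,
        edge_distance=spheroid.edge_distance, geometry=g,
    )
    # ratio/cutoff work on the crop-local label volume but with the
    # full-stack area series so plane indices are absolute
    cutoff = _cutoff_full_frame(labels, spheroid, z0, nuclear.shape[0],
                                params.cutoff_smoothing_window)
    height = approximate_height(slice_area_full, g.dz, params.height_decay_fraction)
    clearing = clearing_metric(cutoff, height, g.dz)
    retained = apply_cutoff(records, cutoff, g.dz)
    return WellAnalysis(
        well_id=well.well_id, gate_reason=GateReason.OK,
        records=records, retained=retained, labels=nuc_full,
        spheroid=sph_full, cutoff=cutoff, height_um=height,
        clearing={
            "approximate_height_um": clearing.approximate_height,
            "cutoff_depth_um": clearing.cutoff_depth,
            "clearing_metric": clearing.clearing_metric,
            "excluded_over_one": clearing.excluded_over_one,
        },
        bbox=gate_result.bbox,
    )


def _cutoff_full_frame(
    labels: LabelVolume,
    spheroid: SpheroidVolume,
    z0: int,
    nz_full: int,
    smoothing_window: int,
) -> CutoffResult:
    """Cutoff on crop-local volumes, re-indexed to absolute plane numbers."""
    local = nuclear_segmentation_cutoff(labels, spheroid, smoothing_window)
    pad_before = np.full(z0, np.nan)
    pad_after = np.full(nz_full - z0 - len(local.ratio_per_slice), np.nan)
    return CutoffResult(
        ratio_per_slice=np.concatenate([pad_before, local.ratio_per_slice, pad_after]),
        smoothed_ratio=np.concatenate([pad_before, local.smoothed_ratio, pad_after]),
        cutoff_slice=None if local.cutoff_slice is None else local.cutoff_slice + z0,
        cutoff_rule_used=local.cutoff_rule_used,
    )


def summarize_well(
    analysis: WellAnalysis,
    label_flags: dict[str, list[bool]] | None = None,
) -> dict:
    """Flat summary row for the plate table."""
    row: dict = {
        "well": analysis.well_id,
        "accepted": analysis.accepted,
        "gate_reason": analysis.gate_reason.value,
        "n_nuclei_total": len(analysis.records),
        "n_nuclei_after_cutoff": len(analysis.retained),
        "cutoff_slice": None,
        "cutoff_rule": None,
        "approx_height_um": analysis.height_um,
        "clearing_metric": None,
        "excluded_over_one": False,
    }
    if analysis.cutoff is not None:
        row["cutoff_slice"] = analysis.cutoff.cutoff_slice
        row["cutoff_rule"] = analysis.cutoff.cutoff_rule_used.value
    if analysis.clearing is not None:
        row["clearing_metric"] = analysis.clearing["clearing_metric"]
        row["excluded_over_one"] = analysis.clearing["excluded_over_one"]
    if label_flags and analysis.spheroid is not None and analysis.retained:
        bins = bin_regions(analysis.retained, analysis.spheroid)
        for ch, flags in label_flags.items():
            row[f"positive_fraction_{ch}"] = _frac(flags)
            for name in ("bottom", "middle", "top"):
                sel = [f for f, b in zip(flags, bins.depth_bin) if b == name]
                row[f"positive_fraction_{ch}_{name}"] = _frac(sel)
            for name in ("outer", "inner"):
                sel = [f for f, b in zip(flags, bins.layer_bin) if b == name]
                row[f"positive_fraction_{ch}_{name}"] = _frac(sel)
    elif label_flags:
        for ch in label_flags:
            row[f"positive_fraction_{ch}"] = 0.0
    return row


def resolve_plate_thresholds(
    analyses: dict[str, WellAnalysis],
    label_channels: tuple[str, ...],
    policy: ThresholdPolicy,
    control_wells: tuple[str, ...] = (),
) -> dict[str, float]:
    """Per-channel plate-wide thresholds from positive-control wells."""
    thresholds = {}
    for ch in label_channels:
        if policy.mode == "fixed":
            thresholds[ch] = policy.resolve()
            continue
        pooled = []
        for well_id in control_wells:
            analysis = analyses.get(well_id)
            if analysis is None or not analysis.accepted:
                continue
            pooled.extend(r.mean_intensity[ch] for r in analysis.retained
                          if ch in r.mean_intensity)
        thresholds[ch] = policy.resolve(np.asarray(pooled))
    return thresholds


def label_flags_for(
    analysis: WellAnalysis, thresholds: dict[str, float]
) -> dict[str, list[bool]]:
    out = {}
    for ch, thr in thresholds.items():
        if analysis.retained and ch in analysis.retained[0].mean_intensity:
            flags, _ = classify_positive(analysis.retained, ch, thr)
        else:
            flags = []
        out[ch] = flags
    return out


def write_well_outputs(
    analysis: WellAnalysis,
    out_dir: str | Path,
    params: PipelineParams,
    label_flags: dict[str, list[bool]] | None = None,
) -> dict[str, Path]:
    """Write the per-spheroid nucleus CSV and metadata JSON."""
    summary = summarize_well(analysis, label_flags)
    meta = dict(summary)
    meta["parameters"] = _params_dict(params)
    if analysis.spheroid is not None:
        g = analysis.spheroid.geometry
        meta["geometry"] = {"dx": g.dx, "dy": g.dy, "dz": g.dz}
    if analysis.spheroid is not None:
        meta["slice_area_um2"] = list(np.asarray(analysis.spheroid.slice_area))
    if analysis.cutoff is not None:
        meta["ratio_per_slice"] = _nan_to_none(analysis.cutoff.ratio_per_slice)
        meta["smoothed_ratio"] = _nan_to_none(analysis.cutoff.smoothed_ratio)
    if analysis.bbox is not None:
        meta["bbox_zyx"] = [list(b) for b in analysis.bbox]
    return write_spheroid_output(
        analysis.well_id, analysis.records, meta, out_dir
    )


def _params_dict(params: PipelineParams) -> dict:
    d = asdict(params)
    seg = d.get("seg", {})
    if seg.get("single_volume_range") is None:
        seg["single_volume_range"] = list(params.seg.resolved_volume_range)
    return d


def _frac(flags: list[bool]) -> float | None:
    return (sum(flags) / len(flags)) if flags else None


def _nan_to_none(arr: np.ndarray) -> list:
    return [None if (isinstance(v, float) and math.isnan(v)) else float(v)
            for v in np.asarray(arr, dtype=float)]
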