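"""Plate-scale orchestration: discovery, parallel per-well dispatch, summary.

Wells are processed independently — one worker handles one well at a time,
mirroring the well-per-core design of plate-scale screening — and a
failure in one well is captured as that well's outcome without disturbing
any other.  The analysis itself is deterministic, and every well writes
only its own files, so outputs are byte-identical regardless of worker
count or completion order.
"""

from __future__ import annotations

import json
import time
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import VoxelGeometry
from .pipeline import (
    PipelineParams,
    WellAnalysis,
    analyze_well,
    label_flags_for,
    resolve_plate_thresholds,
    summarize_well,
    write_well_outputs,
)
from .postseg import ThresholdPolicy
from .stack_io import DEFAULT_FILENAME_PATTERN, discover_wells, load_well


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one plate run."""

    plate_dir: str
    output_dir: str
    filename_pattern: str = DEFAULT_FILENAME_PATTERN
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    threshold_policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    control_wells: tuple[str, ...] = ()
    match_radius_um: float = 6.0
    workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pipeline.counterstain:
            raise ValueError("a counterstain channel must be designated")


@dataclass
class WellOutcome:
    well_id: str
    status: str                  # ok | gated_out | failed
    reason: str = ""
    output_paths: dict = field(default_factory=dict)
    elapsed_s: float = 0.0


def _process_one_well(args: tuple) -> tuple[str, WellAnalysis | None, WellOutcome]:
    """Worker: load and analyze one well; never raises."""
    descriptor, config = args
    t0 = time.perf_counter()
    try:
        well = load_well(descriptor, geometry=config.geometry)
        analysis = analyze_well(well, config.pipeline)
        status = "ok" if analysis.accepted else "gated_out"
        outcome = WellOutcome(
            well_id=descriptor.well_id,
            status=status,
            reason=analysis.gate_reason.value,
            elapsed_s=time.perf_counter() - t0,
        )
        return descriptor.well_id, analysis, outcome
    except Exception:
        outcome = WellOutcome(
            well_id=descriptor.well_id,
            status="failed",
            reason=traceback.format_exc(limit=5),
            elapsed_s=time.perf_counter() - t0,
        )
        return descriptor.well_id, None, outcome


def run_plate(config: RunConfig) -> tuple[list[WellOutcome], pd.DataFrame]:
    """Process every complete well of a plate and write all outputs.

    Per-well pipeline: load -> gate -> segment nuclei -> whole spheroid ->
    quality metrics -> cutoff filter -> label thresholding -> write.
    Label thresholds are plate-wide, pooled from the configured
    positive-control wells after all wells are analyzed.  Returns the
    outcomes and the plate summary table (also written to
    ``output_dir/plate_summary.csv``).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    descriptors = discover_wells(config.plate_dir, config.filename_pattern, warnings)

    outcomes: dict[str, WellOutcome] = {}
    analyses: dict[str, WellAnalysis] = {}
    runnable = []
    for d in descriptors:
        if not d.complete:
            outcomes[d.well_id] = WellOutcome(
                well_id=d.well_id, status="failed",
                reason="incomplete image set: " + "; ".join(d.issues),
            )
        else:
            runnable.append(d)

    tasks = [(d, config) for d in runnable]
    if config.workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(_process_one_well, tasks))
    else:
        results = [_process_one_well(t) for t in tasks]
    for well_id, analysis, outcome in results:
        outcomes[well_id] = outcome
        if analysis is not None:
            analyses[well_id] = analysis

    label_channels = config.pipeline.label_channels
    thresholds: dict[str, float] = {}
    if label_channels:
        try:
            thresholds = resolve_plate_thresholds(
                analyses, label_channels, config.threshold_policy,
                config.control_wells,
            )
        except ValueError as exc:
            if config.threshold_policy.mode != "fixed" and not config.control_wells:
                raise ValueError(
                    "label channels configured but no positive-control wells "
                    "designated for the plate_control threshold policy"
                ) from exc
            raise

    rows = []
    for well_id in sorted(analyses):
        analysis = analyses[well_id]
        flags = label_flags_for(analysis, thresholds) if thresholds else None
        paths = write_well_outputs(analysis, out_dir, config.pipeline, flags)
        outcomes[well_id].output_paths = {k: str(v) for k, v in paths.items()}
        rows.append(summarize_well(analysis, flags))
    for well_id in sorted(outcomes):
        if outcomes[well_id].status == "failed":
            rows.append({"well": well_id, "accepted": False,
                         "gate_reason": "failed"})

    summary = pd.DataFrame(rows)
    if not summary.empty:
        summary = summary.sort_values("well").reset_index(drop=True)
    summary.to_csv(out_dir / "plate_summary.csv", index=False)
    if thresholds:
        with open(out_dir / "plate_thresholds.json", "w") as fh:
            json.dump(thresholds, fh, indent=1, sort_keys=True)
            fh.write("\n")
    if warnings:
        (out_dir / "discovery_warnings.txt").write_text("\n".join(warnings) + "\n")
    return [outcomes[w] for w in sorted(outcomes)], summary
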