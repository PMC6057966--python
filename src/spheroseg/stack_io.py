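"""Plate discovery, TIFF stack loading, and per-spheroid output writing.

A plate folder holds one single-plane 16-bit grayscale TIFF per
(well, channel, z-plane).  File names are parsed with a configurable
regular expression carrying named capture groups; the default matches
high-content exports of the form ``r02c03f01p12-ch1...tiff`` where the
well identity is row/column, the field index is ignored (one field covers
one spheroid) and planes count up from the shallowest imaged plane.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .geometry import DEFAULT_GEOMETRY, VoxelGeometry

#: Default filename pattern: named groups ``row``/``col`` (or ``well``),
#: ``channel`` and ``plane`` are required; everything else is ignored.
DEFAULT_FILENAME_PATTERN = (
    r"r(?P<row>\d+)c(?P<col>\d+)f\d+p(?P<plane>\d+)-ch(?P<channel>\d+).*\.tiff?$"
)


@dataclass
class ImageStack:
    """One channel's 3D intensity volume, indexed ``(z, y, x)``.

    z index 0 is the shallowest imaged plane (closest to the objective /
    plate bottom); depth increases with z index.
    """

    voxels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("ImageStack requires a 3D (z, y, x) array")
        if self.voxels.shape[0] < 2:
            raise ValueError("ImageStack requires at least 2 z-planes")
        if np.issubdtype(self.voxels.dtype, np.integer) and self.voxels.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class WellImageSet:
    """All channels of one well, sharing dimensions and geometry."""

    plate_id: str
    well_id: str
    channels: dict[str, ImageStack]
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        shapes = {c: s.shape for c, s in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel dimensions differ: {shapes}")

    def channel(self, name: str) -> ImageStack:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"well {self.well_id} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None


@dataclass
class WellDescriptor:
    """Files discovered for one well, grouped by channel, sorted by plane."""

    well_id: str
    channels: dict[str, list[Path]]
    plane_numbers: dict[str, list[int]]
    complete: bool
    issues: list[str] = field(default_factory=list)

    @property
    def n_planes(self) -> int:
        return max((len(v) for v in self.channels.values()), default=0)


def _well_from_match(m: re.Match) -> str:
    g = m.groupdict()
    if g.get("well"):
        return g["well"]
    row, col = int(g["row"]), int(g["col"])
    return f"{chr(ord('A') + row - 1)}{col:02d}"


def discover_wells(
    plate_dir: str | Path,
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
    warnings: list[str] | None = None,
) -> list[WellDescriptor]:
    """Scan a plate folder and group TIFF planes into per-well descriptors.

    Parameters
    ----------
    plate_dir : path
        Folder of single-plane TIFFs.
    filename_pattern : str
        Regex with named groups ``plane``, ``channel`` and either ``well``
        or ``row``+``col``.  Matched against the file name only.
    warnings : list, optional
        If given, receives one message per file that matched the pattern
        but could not be parsed.

    Returns
    -------
    list of WellDescriptor, sorted by well id.  Wells whose channels do
    not share an identical, gap-free plane set are flagged
    ``complete=False`` with an explanatory issue; they are reported, not
    dropped.
    """
    plate_dir = Path(plate_dir)
    if not plate_dir.is_dir():
        raise FileNotFoundError(f"plate directory not readable: {plate_dir}")
    pattern = re.compile(filename_pattern)

    grouped: dict[str, dict[str, dict[int, Path]]] = {}
    for path in sorted(plate_dir.iterdir()):
        if not path.is_file():
            continue
        m = pattern.match(path.name)
        if m is None:
            continue
        try:
            well = _well_from_match(m)
            channel = m.group("channel")
            plane = int(m.group("plane"))
        except (IndexError, KeyError, ValueError) as exc:
            if warnings is not None:
                warnings.append(f"{path.name}: unparsable ({exc}); excluded")
            continue
        slot = grouped.setdefault(well, {}).setdefault(channel, {})
        if plane in slot and warnings is not None:
            warnings.append(f"{path.name}: duplicate plane {plane}; keeping first")
        slot.setdefault(plane, path)

    descriptors = []
    for well in sorted(grouped):
        by_channel = grouped[well]
        plane_sets = {ch: sorted(planes) for ch, planes in by_channel.items()}
        issues = []
        ref = None
        for ch in sorted(plane_sets):
            planes = plane_sets[ch]
            if planes != list(range(planes[0], planes[0] + len(planes))):
                issues.append(f"channel {ch}: plane numbering has gaps")
            if ref is None:
                ref = planes
            elif planes != ref:
                issues.append(f"channel {ch}: plane set differs from first channel")
        descriptors.append(
            WellDescriptor(
                well_id=well,
                channels={
                    ch: [by_channel[ch][p] for p in plane_sets[ch]]
                    for ch in sorted(by_channel)
                },
                plane_numbers=plane_sets,
                complete=not issues,
                issues=issues,
            )
        )
    return descriptors


def _read_plane(path: Path) -> np.ndarray:
    plane = tifffile.imread(path)
    if plane.ndim != 2:
        raise ValueError(f"{path}: expected a single grayscale plane, got shape {plane.shape}")
    if plane.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit grayscale TIFF, got dtype {plane.dtype}")
    return plane


def load_well(
    descriptor: WellDescriptor,
    geometry: VoxelGeometry = DEFAULT_GEOMETRY,
    plate_id: str = "",
) -> WellImageSet:
    """Assemble a :class:`WellImageSet` from a discovered descriptor.

    Planes are stacked in ascending plane-number order (shallowest first).
    Bit depth is validated per file; a wrong-depth or RGB plane raises
    with the offending file named.
    """
    channels = {}
    shape = None
    for ch, paths in descriptor.channels.items():
        planes = [_read_plane(p) for p in paths]
        for p, arr in zip(paths, planes):
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"{p}: plane shape {arr.shape} != expected {shape}")
        channels[ch] = ImageStack(np.stack(planes, axis=0), geometry)
    return WellImageSet(plate_id=plate_id, well_id=descriptor.well_id,
                        channels=channels, geometry=geometry)


NUCLEUS_TABLE_BASE_COLUMNS = [
    "label", "centroid_x_um", "centroid_y_um", "centroid_z_um",
    "volume_um3", "voxel_count", "distance_to_edge_um",
    "z_first", "z_last", "provenance",
]


def write_spheroid_output(
    well_id: str,
    nuclei: Iterable,
    spheroid_summary: Mapping,
    out_dir: str | Path,
    channel_names: list[str] | None = None,
) -> dict[str, Path]:
    """Write one spheroid's nucleus table (CSV) and metadata document (JSON).

    The nucleus table has one row per nucleus: label, centroid x/y/z in um,
    volume in um^3, per-channel mean intensity, distance to the spheroid
    edge in um.  The JSON document carries the spheroid-level summary
    (per-slice areas, cutoff, height, clearing metric, flags, parameters).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = list(nuclei)
    labels = [r.label for r in records]
    if len(labels) != len(set(labels)):
        raise ValueError("nucleus labels must be unique")
    if channel_names is None:
        seen: dict[str, None] = {}
        for r in records:
            for ch in r.mean_intensity:
                seen.setdefault(ch)
        channel_names = list(seen)

    columns = NUCLEUS_TABLE_BASE_COLUMNS + [f"mean_intensity_{c}" for c in channel_names]
    rows = []
    for r in records:
        row = {
            "label": r.label,
            "centroid_x_um": r.centroid[0],
            "centroid_y_um": r.centroid[1],
            "centroid_z_um": r.centroid[2],
            "volume_um3": r.volume,
            "voxel_count": r.voxel_count,
            "distance_to_edge_um": r.distance_to_edge,
            "z_first": r.z_slice_span[0],
            "z_last": r.z_slice_span[1],
            "provenance": r.provenance,
        }
        for c in channel_names:
            row[f"mean_intensity_{c}"] = r.mean_intensity.get(c, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows, columns=columns)

    csv_path = out_dir / f"{well_id}_nuclei.csv"
    table.to_csv(csv_path, index=False)
    meta_path = out_dir / f"{well_id}_spheroid.json"
    with open(meta_path, "w") as fh:
        json.dump(_jsonable(dict(spheroid_summary)), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"nuclei": csv_path, "spheroid": meta_path}


def read_spheroid_output(out_dir: str | Path, well_id: str) -> tuple[pd.DataFrame, dict]:
    """Reload the pair written by :func:`write_spheroid_output`."""
    out_dir = Path(out_dir)
    table = pd.read_csv(out_dir / f"{well_id}_nuclei.csv",
                        float_precision="round_trip")
    with open(out_dir / f"{well_id}_spheroid.json") as fh:
        meta = json.load(fh)
    return table, meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
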