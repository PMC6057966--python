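"""Physical voxel geometry shared by every stage of the pipeline.

All distances, volumes and areas in this package are expressed in physical
micrometres; voxel indices are only ever an addressing scheme.  The default
geometry is a high-content spinning-disk confocal acquisition with a 20x
water objective and 2x camera binning (0.64 um xy pixels) and a sparse 5 um
z-step, under which a ~12 um nucleus spans 2-3 z-planes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one voxel, in micrometres per axis.

    Attributes
    ----------
    dx, dy : float
        In-plane pixel pitch (um).  Default 0.64 um.
    dz : float
        Spacing between consecutive z-planes (um).  Default 5.0 um.
    """

    dx: float = 0.64
    dy: float = 0.64
    dz: float = 5.0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel spacings must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return self.dx * self.dy * self.dz

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel in um^2."""
        return self.dx * self.dy

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        """Per-axis spacing in (z, y, x) array order, for scipy/skimage calls."""
        return (self.dz, self.dy, self.dx)

    def centroid_um(self, zyx: tuple[float, float, float]) -> tuple[float, float, float]:
        """Convert a (z, y, x) index-space point to (x, y, z) um.

        Pixel centres sit at (i + 0.5) * spacing with the origin at the
        corner of the stack, so integer index 0 maps to half a spacing.
        """
        z, y, x = zyx
        return ((x + 0.5) * self.dx, (y + 0.5) * self.dy, (z + 0.5) * self.dz)


DEFAULT_GEOMETRY = VoxelGeometry()
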