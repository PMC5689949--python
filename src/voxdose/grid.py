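"""Voxel lattice geometry."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class GridSpec:
    """A regular cubic-voxel lattice.

    The default lattice is 128 x 128 x 600 voxels with a 0.3125 cm voxel
    side, i.e. a 40 x 40 x 187.5 cm field of view — wide enough for a
    whole-body phantom and tall enough for adult heights.

    Axis convention: arrays are indexed ``[ix, iy, iz]`` with x the
    left-right body axis, y the anterior-posterior axis, and z the
    feet-to-head axis.  Physical coordinates are in cm with the origin at
    the corner of voxel (0, 0, 0); voxel ``i`` spans
    ``[i * voxel_side, (i + 1) * voxel_side)``.
    """

    nx: int = 128
    ny: int = 128
    nz: int = 600
    voxel_side: float = 0.3125  # cm

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValidationError("voxel counts must all be >= 1")
        if self.voxel_side <= 0:
            raise ValidationError("voxel_side must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in cm^3."""
        return self.voxel_side**3

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical lattice extent (cm) along each axis."""
        s = self.voxel_side
        return (self.nx * s, self.ny * s, self.nz * s)

    def voxel_index(self, points):
        """Map physical points (n, 3) in cm to integer voxel indices (n, 3).

        Points outside the lattice map to out-of-bounds indices; callers
        decide how to treat them.
        """
        import numpy as np

        return np.floor(np.asarray(points) / self.voxel_side).astype(np.int64)
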