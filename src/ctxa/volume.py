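"""Voxel-grid containers shared by every pipeline stage.

Conventions (used everywhere in the package):

* arrays are indexed ``[ix, iy, iz]`` with x = left-right, y =
  anterior-posterior and z = inferior-superior (axial slices stacked along z,
  z increasing inferior to superior);
* voxel indices are 0-based and voxel-centred: voxel ``(i, j, k)`` sits at
  ``(i*dx, j*dy, k*dz)`` mm;
* intervals (boxes, slice ranges) are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

#: default acquisition geometry: 40 cm display FOV on a 512 grid (0.781 mm
#: pixels), contiguous 3 mm axial slices.
DEFAULT_SPACING = (0.781, 0.781, 3.0)


@dataclass
class _Grid3D:
    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


@dataclass
class CTVolume(_Grid3D):
    """Scanner-side input: CT numbers (HU) on a voxel grid."""


@dataclass
class CalibratedVolume(_Grid3D):
    """CT grid mapped to equivalent aqueous K2HPO4 density, mg/cm3.

    Equivalent density can legitimately be negative (fat-rich tissue), so no
    lower bound is enforced.
    """


@dataclass
class VoxelBox:
    """Axis-aligned sub-volume in 0-based, half-open voxel indices."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "VoxelBox":
        return cls((0, shape[0]), (0, shape[1]), (0, shape[2]))

    @classmethod
    def from_mm(cls, lo_mm, hi_mm, spacing) -> "VoxelBox":
        """Convert half-open mm bounds to voxel indices (nearest centres)."""
        lo = [int(np.ceil(l / s - 0.5)) for l, s in zip(lo_mm, spacing)]
        hi = [int(np.floor(h / s + 0.5)) for h, s in zip(hi_mm, spacing)]
        return cls((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]))

    def validate(self, shape: tuple[int, int, int]) -> None:
        for (lo, hi), n, name in zip((self.x, self.y, self.z), shape, "xyz"):
            if not (0 <= lo < hi <= n):
                raise GeometryError(
                    f"box {name}-range [{lo}, {hi}) outside grid of size {n}"
                )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))

    def center_index(self) -> tuple[float, float, float]:
        return tuple((lo + hi - 1) / 2.0 for lo, hi in (self.x, self.y, self.z))


@dataclass
class BoneMask(_Grid3D):
    """Boolean femur mask aligned to a :class:`CalibratedVolume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.dtype != bool:
            self.values = self.values.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_cm3

    def coordinates_mm(self) -> np.ndarray:
        """(N, 3) mm coordinates of masked voxel centres."""
        idx = np.argwhere(self.values)
        return idx * np.asarray(self.spacing)
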