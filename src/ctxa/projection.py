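"""Parallel-beam coronal projection of the oriented bone volume.

Each pixel of the DXA-like image is the mineral mass summed along the
anteroposterior line through it, together with the bone path volume along
that line.  Because the pixel lattice coincides with the oriented voxel
lattice, the projection is a plain column sum and conserves mass exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .orientation import OrientedBoneVolume

log = logging.getLogger(__name__)


@dataclass
class ProjectionImage:
    """Per-pixel mass (g) and bone path volume (cm3) on the (x, z) lattice."""

    mass_g: np.ndarray  # (nx, nz)
    volume_cm3: np.ndarray  # (nx, nz)
    pixel_spacing_mm: tuple[float, float]  # (dx, dz)

    def __post_init__(self):
        if self.mass_g.shape != self.volume_cm3.shape:
            raise ValueError("mass and volume maps must share a shape")
        if np.any(self.volume_cm3 < 0):
            raise ValueError("negative projected path volume")
        if np.any(self.mass_g < 0):
            # net-negative columns can only arise from noisy sub-zero marrow
            # densities; keep them so mass stays exactly conserved
            log.warning("projection contains net-negative mass columns")

    @property
    def pixel_area_cm2(self) -> float:
        dx, dz = self.pixel_spacing_mm
        return (dx / 10.0) * (dz / 10.0)

    @property
    def silhouette(self) -> np.ndarray:
        """Pixels through which at least one bone voxel projects."""
        return self.volume_cm3 > 0

    @property
    def abmd_g_cm2(self) -> np.ndarray:
        """Areal BMD map; exactly zero where no bone projects."""
        return np.where(self.silhouette, self.mass_g / self.pixel_area_cm2, 0.0)

    @property
    def pathlength_cm(self) -> np.ndarray:
        return np.where(self.silhouette, self.volume_cm3 / self.pixel_area_cm2, 0.0)

    @property
    def total_mass_g(self) -> float:
        return float(self.mass_g.sum())


def project_coronal(ov: OrientedBoneVolume) -> ProjectionImage:
    """Sum bone voxels along +y (anteroposterior) into a 2D image.

    mass(x, z) = sum_y density * voxel_volume / 1000 (mg -> g), and
    volume(x, z) = bone voxel count * voxel volume, both over the mask only.
    Background pixels are exactly zero.
    """
    if not ov.mask.any():
        log.warning("projecting an empty mask: image is all zero")
    masked = ov.masked_density()
    vox_cm3 = ov.voxel_volume_cm3
    mass = masked.sum(axis=1) * vox_cm3 / 1000.0
    volume = ov.mask.sum(axis=1) * vox_cm3
    return ProjectionImage(mass, volume, (ov.spacing_mm, ov.spacing_mm))
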