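"""Standard-pose rotation of the segmented femur.

The segmented bone set is rotated so that the femoral shaft is vertical in
the coronal and sagittal views and the femoral neck is horizontal in the
axial view.  Axes are estimated by principal-axis analysis of the mask voxel
coordinates: the shaft from the distal 40% of the mask, the neck from the
band around the narrowest cross-section between the head centre and the
shaft axis.  In the standard pose the femoral head lies on the +x side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import OrientationError, ResourceError
from .volume import BoneMask, CalibratedVolume

log = logging.getLogger(__name__)

#: sentinel stored outside the mask in an OrientedBoneVolume (0 is a valid
#: equivalent density, so it cannot double as "not bone")
NOT_BONE = np.nan

#: minimum large-to-second principal-eigenvalue ratio before an axis counts
#: as well defined
_MIN_ANISOTROPY = 1.5


@dataclass
class RigidRotation:
    """Rotation taking scanner coordinates into the standard pose."""

    matrix: np.ndarray  # 3x3, rows are the standard-frame axes
    center_mm: np.ndarray  # centre of rotation, scanner frame
    shaft_axis: np.ndarray  # pre-rotation unit vector, maps to +z
    neck_axis: np.ndarray  # pre-rotation unit vector, horizontal component maps to +x

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("rotation matrix must be 3x3")
        if not np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix must be orthonormal")
        if not np.isclose(np.linalg.det(self.matrix), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must be proper (det +1)")
        self.center_mm = np.asarray(self.center_mm, dtype=float)

    @classmethod
    def identity(cls, center_mm=(0.0, 0.0, 0.0)) -> "RigidRotation":
        return cls(np.eye(3), np.asarray(center_mm), np.array([0.0, 0.0, 1.0]),
                   np.array([1.0, 0.0, 0.0]))

    @classmethod
    def from_axes(cls, shaft_axis, neck_axis, center_mm) -> "RigidRotation":
        """Build the rotation mapping shaft -> +z and the neck's component
        orthogonal to the shaft -> +x."""
        r3 = np.asarray(shaft_axis, float)
        r3 = r3 / np.linalg.norm(r3)
        n = np.asarray(neck_axis, float)
        n = n / np.linalg.norm(n)
        n_perp = n - (n @ r3) * r3
        norm = np.linalg.norm(n_perp)
        if norm < 1e-3:
            raise OrientationError(
                "neck axis is parallel to the shaft axis; supply manual angles"
            )
        r1 = n_perp / norm
        r2 = np.cross(r3, r1)
        return cls(np.vstack([r1, r2, r3]), np.asarray(center_mm), r3, n)

    def angle_to_identity_deg(self) -> float:
        cos = (np.trace(self.matrix) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def apply_points(self, points_mm: np.ndarray) -> np.ndarray:
        return (points_mm - self.center_mm) @ self.matrix.T


@dataclass
class OrientedBoneVolume:
    """Masked density resampled isotropically in the standard pose.

    ``density`` holds NaN outside the mask; use :attr:`total_mass_g` or the
    projection stage, both of which go through the mask.
    """

    density: np.ndarray  # mg/cm3, NaN outside mask
    mask: np.ndarray  # bool
    spacing_mm: float  # isotropic
    rotation: RigidRotation

    def __post_init__(self):
        if self.density.shape != self.mask.shape:
            raise ValueError("density and mask shapes differ")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.spacing_mm / 10.0) ** 3

    @property
    def total_mass_g(self) -> float:
        """Mineral mass in g: sum of density x voxel volume over the mask."""
        return float(np.sum(self.density[self.mask]) * self.voxel_volume_cm3 / 1000.0)

    def masked_density(self) -> np.ndarray:
        """Density with zeros (not NaN) outside the mask, for arithmetic."""
        return np.where(self.mask, np.nan_to_num(self.density), 0.0)

    def with_mask(self, mask: np.ndarray) -> "OrientedBoneVolume":
        """Same grid restricted to a sub-mask (used for compartments)."""
        sub = self.mask & mask
        density = np.where(sub, np.nan_to_num(self.density), NOT_BONE)
        return OrientedBoneVolume(density, sub, self.spacing_mm, self.rotation)


def _principal_axis(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal axis of a point cloud and its eigenvalue ratio."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    ratio = evals[-1] / max(evals[-2], 1e-12)
    return evecs[:, -1], float(ratio)


def estimate_standard_rotation(
    mask: BoneMask,
    min_axial_slices: int = 20,
) -> RigidRotation:
    """Estimate shaft and neck axes from the mask geometry.

    Shaft: the distal (lowest-z) 40% of the mask contributes one robust
    centre per axial slice (the centroid of the near-maximal inscribed-disk
    plateau, which trochanteric prominences cannot shift); the shaft axis is
    the principal axis of those centres, oriented superiorly.  Neck: the
    head centre is the centre of the largest inscribed sphere in the
    proximal mask, and the neck axis is the principal axis of the head+neck
    assembly - proximal voxels lying radially outside the shaft cylinder -
    which is symmetric about the true neck axis.  Degenerate geometry (an
    isotropic blob) raises :class:`OrientationError` so the operator can
    supply manual angles.
    """
    coords = mask.coordinates_mm()
    if coords.shape[0] == 0:
        raise OrientationError("empty mask")
    n_slices = np.unique(np.argwhere(mask.values)[:, 2]).size
    if n_slices < min_axial_slices and mask.spacing[2] >= 1.0:
        log.warning(
            "mask spans only %d axial slices (<%d); axis estimates may be unstable",
            n_slices, min_axial_slices,
        )

    dx, dy, dz = mask.spacing
    z = coords[:, 2]
    z_cut = z.min() + 0.4 * (z.max() - z.min())
    distal = coords[z <= z_cut]
    if len(distal) < 10:
        raise OrientationError("too few distal voxels for a shaft axis")
    _, ratio = _principal_axis(distal)
    if ratio < _MIN_ANISOTROPY:
        raise OrientationError(
            f"distal mask has no well-defined long axis (eigenvalue ratio {ratio:.2f}); "
            "supply manual shaft/neck angles"
        )

    centers = []
    radii = []
    for k in range(mask.shape[2]):
        if k * dz > z_cut or not mask.values[:, :, k].any():
            continue
        edt2 = ndimage.distance_transform_edt(mask.values[:, :, k], sampling=(dx, dy))
        m = edt2.max()
        if m < 2 * max(dx, dy):
            continue
        plateau = edt2 >= 0.8 * m
        ii, jj = np.nonzero(plateau)
        centers.append([ii.mean() * dx, jj.mean() * dy, k * dz])
        radii.append(m)
    if len(centers) < 3:
        raise OrientationError("too few usable distal slices for a shaft axis")
    centers = np.asarray(centers)
    shaft_radius = float(np.median(radii))
    shaft_axis, _ = _principal_axis(centers)
    if shaft_axis[2] < 0:
        shaft_axis = -shaft_axis
    shaft_point = centers.mean(axis=0)

    # head centre: largest inscribed sphere in the proximal mask
    edt = ndimage.distance_transform_edt(mask.values, sampling=mask.spacing)
    z_grid = np.arange(mask.shape[2]) * dz
    edt_prox = np.where(z_grid[None, None, :] >= z_cut, edt, 0.0)
    head_idx = np.unravel_index(np.argmax(edt_prox), mask.shape)
    head_center = np.asarray(head_idx) * np.asarray(mask.spacing)
    if np.linalg.norm(head_center - shaft_point) < 1e-6:
        raise OrientationError("head centre coincides with the shaft axis")

    # head+neck assembly: proximal voxels radially outside the shaft
    rel = coords - shaft_point
    radial = np.linalg.norm(rel - (rel @ shaft_axis)[:, None] * shaft_axis, axis=1)
    sel = (z >= z_cut) & (radial > shaft_radius + max(dx, dy))
    assembly = coords[sel]
    if len(assembly) < 50:
        raise OrientationError("no head/neck mass outside the shaft cylinder")
    neck_axis, neck_ratio = _principal_axis(assembly)
    if neck_ratio < 1.1:
        raise OrientationError(
            f"head/neck assembly has no well-defined axis (eigenvalue ratio {neck_ratio:.2f})"
        )
    if neck_axis @ (head_center - assembly.mean(axis=0)) < 0:  # point at the head
        neck_axis = -neck_axis

    return RigidRotation.from_axes(shaft_axis, neck_axis, coords.mean(axis=0))


def apply_rotation(
    volume: CalibratedVolume,
    mask: BoneMask,
    rot: RigidRotation,
    out_spacing_mm: float | None = None,
    max_voxels: int = 200_000_000,
    pad_mm: float = 3.0,
) -> OrientedBoneVolume:
    """Resample the masked density onto an isotropic standard-pose grid.

    Density and mask occupancy are interpolated trilinearly; a voxel belongs
    to the oriented mask when its interpolated occupancy is at least 0.5, and
    its density is the occupancy-normalised interpolated masked density
    (which keeps boundary voxels at interior-like densities and conserves
    total mass to about the percent level).
    """
    if out_spacing_mm is None:
        out_spacing_mm = float(min(volume.spacing[0], volume.spacing[1]))
    if not mask.values.any():
        raise OrientationError("cannot rotate an empty mask")

    coords = mask.coordinates_mm()
    std = rot.apply_points(coords)
    lo = std.min(axis=0) - pad_mm
    hi = std.max(axis=0) + pad_mm
    shape = np.maximum(np.ceil((hi - lo) / out_spacing_mm).astype(int) + 1, 1)
    if int(np.prod(shape)) > max_voxels:
        raise ResourceError(
            f"oriented grid of {np.prod(shape)} voxels exceeds bound {max_voxels}"
        )

    # output index -> scanner voxel index: w = R^T s + c, s = lo + i*h
    spacing = np.asarray(volume.spacing)
    A = (rot.matrix.T * out_spacing_mm) / spacing[:, None]
    offset = (rot.matrix.T @ lo + rot.center_mm) / spacing

    masked = np.where(mask.values, volume.values, 0.0).astype(float)
    occupancy = mask.values.astype(float)
    density_r = ndimage.affine_transform(
        masked, A, offset=offset, output_shape=tuple(shape), order=1, cval=0.0
    )
    occ_r = ndimage.affine_transform(
        occupancy, A, offset=offset, output_shape=tuple(shape), order=1, cval=0.0
    )
    out_mask = occ_r >= 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(out_mask, density_r / occ_r, NOT_BONE)
    return OrientedBoneVolume(density, out_mask, float(out_spacing_mm), rot)
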