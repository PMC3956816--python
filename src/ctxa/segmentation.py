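"""Adaptive-threshold segmentation of the proximal femur.

Bone is separated from surrounding tissue by a three-parameter adaptive
algorithm: a hard floor below which a voxel can never be bone (default
-250 mg/cm3), the width of the local neighbourhood used to adapt the
threshold (default 5 voxels), and an initial seed threshold (default
120 mg/cm3).  The refined mask is then closed into a single envelope so that
everything inside the outer cortex - marrow included - counts as bone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .volume import BoneMask, CalibratedVolume, VoxelBox

log = logging.getLogger(__name__)

_MAX_REFINE_ITERATIONS = 50


@dataclass(frozen=True)
class SegmentationParams:
    """The three knobs of the adaptive segmentation."""

    floor_threshold: float = -250.0  # mg/cm3; never bone below this
    neighborhood_width: int = 5  # voxels, odd
    seed_threshold: float = 120.0  # mg/cm3; initial bone/not-bone split

    def __post_init__(self):
        if self.floor_threshold > self.seed_threshold:
            raise ValueError("floor_threshold must not exceed seed_threshold")
        if self.neighborhood_width < 3 or self.neighborhood_width % 2 == 0:
            raise ValueError("neighborhood_width must be odd and >= 3")


def segment_bone(
    volume: CalibratedVolume,
    box: VoxelBox | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> BoneMask:
    """Adaptive local-mean thresholding with a hard floor, restricted to ``box``.

    Seeding classifies voxels above the seed threshold as tentative bone.
    The refinement then re-labels each voxel lying within the neighbourhood
    cube of current bone: it stays (or becomes) bone when its density
    reaches the local mean density over that cube - partial-volume boundary
    voxels that are mostly background fall below the local mean and are
    pruned, while mostly-bone voxels are admitted - and nothing at or below
    the floor is ever bone.  Sweeps repeat until the label set is stable
    (at most 50 sweeps).  An empty result is legitimate, not an error.
    """
    if box is None:
        box = VoxelBox.full(volume.shape)
    box.validate(volume.shape)

    density = volume.values.astype(float)
    local_mean = ndimage.uniform_filter(
        density, size=params.neighborhood_width, mode="nearest"
    )
    admissible = (
        (density >= np.maximum(params.floor_threshold, local_mean))
        & (density > params.floor_threshold)
    )
    neighborhood = np.ones((params.neighborhood_width,) * 3, dtype=bool)

    labels = density > params.seed_threshold
    for _ in range(_MAX_REFINE_ITERATIONS):
        near_bone = ndimage.binary_dilation(labels, structure=neighborhood)
        refined = admissible & near_bone
        if np.array_equal(refined, labels):
            break
        labels = refined

    out = np.zeros(volume.shape, dtype=bool)
    out[box.slices] = labels[box.slices]
    if not out.any():
        log.warning("segmentation produced an empty mask")
    return BoneMask(out, volume.spacing)


def fill_cortical_envelope(
    mask: BoneMask,
    box: VoxelBox | None = None,
    keep_largest: bool = True,
) -> BoneMask:
    """Absorb everything enclosed by the cortex into the mask.

    Per-axial-slice hole filling, then 3D hole filling (the 2D pass guarantees
    the envelope closes even on strongly anisotropic grids where a marrow
    cavity stays 3D-connected to the outside through the slice gaps).  With
    ``keep_largest`` the largest 26-connected component intersecting ``box``
    is retained; ties break toward the component nearest the box centre.
    """
    if not mask.values.any():
        log.warning("fill_cortical_envelope called on an empty mask; returned unchanged")
        return BoneMask(mask.values.copy(), mask.spacing)

    filled = mask.values.copy()
    for k in range(filled.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(filled[:, :, k])
    filled = ndimage.binary_fill_holes(filled)

    if keep_largest:
        if box is None:
            box = VoxelBox.full(mask.shape)
        box.validate(mask.shape)
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        labeled, n = ndimage.label(filled, structure=structure)
        if n > 1:
            in_box = np.zeros_like(filled)
            in_box[box.slices] = True
            candidates = [
                i for i in range(1, n + 1) if np.any((labeled == i) & in_box)
            ] or list(range(1, n + 1))
            sizes = ndimage.sum_labels(filled, labeled, candidates)
            best_size = sizes.max()
            tied = [c for c, s in zip(candidates, sizes) if s == best_size]
            if len(tied) > 1:
                center = np.asarray(box.center_index())
                centroids = ndimage.center_of_mass(filled, labeled, tied)
                tied = [
                    c for c, _ in sorted(
                        zip(tied, centroids),
                        key=lambda cc: np.linalg.norm(np.asarray(cc[1]) - center),
                    )
                ]
            filled = labeled == tied[0]
    return BoneMask(filled, mask.spacing)
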