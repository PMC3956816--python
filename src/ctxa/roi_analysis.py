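"""Standard hip ROIs on the projected image and compartment measurements.

Regions mirror the common DXA ones - Femoral Neck (a rotatable box across
the neck), Trochanter, Intertrochanter, and Total Hip as their exact union.
Landmarks are found automatically on the background-free silhouette (head =
largest inscribed circle; neck axis = minimal-width cut through the isthmus;
the inferior boundary sits at the lower junction of the lesser trochanter
and the shaft) and every parameter can be overridden by the operator, so a
landmark failure never blocks measurement.

Voxels are classified cortical when their equivalent density reaches the
compartment threshold (default 350 mg/cm3), trabecular otherwise; each
compartment is re-projected through the same ROIs so that cortical +
trabecular mass and volume add up to the integral values exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import LandmarkError, UndefinedMeasureError
from .orientation import OrientedBoneVolume
from .projection import ProjectionImage, project_coronal

log = logging.getLogger(__name__)

ROI_NAMES = ("neck", "trochanter", "intertrochanter", "total_hip")
_LABELS = {"neck": 1, "trochanter": 2, "intertrochanter": 3, "head": 4}


@dataclass(frozen=True)
class CompartmentParams:
    cortical_threshold: float = 350.0  # mg/cm3

    def __post_init__(self):
        if self.cortical_threshold <= 0:
            raise ValueError("cortical threshold must be positive")


@dataclass
class ROIResult:
    """Measurements for one ROI and compartment."""

    roi: str
    compartment: str  # integral | cortical | trabecular
    mass_g: float
    area_cm2: float
    volume_cm3: float

    @property
    def abmd_g_cm2(self) -> float:
        return self.mass_g / self.area_cm2 if self.area_cm2 > 0 else 0.0

    @property
    def vbmd_mg_cm3(self) -> float:
        return 1000.0 * self.mass_g / self.volume_cm3 if self.volume_cm3 > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "roi": self.roi,
            "compartment": self.compartment,
            "abmd_g_cm2": self.abmd_g_cm2,
            "vbmd_mg_cm3": self.vbmd_mg_cm3,
            "mass_g": self.mass_g,
            "area_cm2": self.area_cm2,
            "volume_cm3": self.volume_cm3,
        }


@dataclass
class HipROISet:
    """Pixel label map plus the geometric parameters that generated it.

    Labels: 0 background/excluded shaft, 1 neck, 2 trochanter,
    3 intertrochanter, 4 head (displayed regions only; the head is not part
    of Total Hip).  The three measured ROIs are pairwise disjoint by
    construction and Total Hip is their exact union.
    """

    labels: np.ndarray  # (nx, nz) int8
    pixel_spacing_mm: tuple[float, float]
    neck_center_mm: tuple[float, float]  # (x, z), toward-head axis origin
    neck_angle_deg: float  # angle of the toward-head neck axis from +x
    neck_box_width_mm: float  # along the axis
    neck_box_length_mm: float  # across the axis
    boundary_z_mm: float  # inferior limit of the Intertrochanter ROI
    mirrored: bool = False

    def pixels(self, roi: str) -> np.ndarray:
        if roi == "total_hip":
            return (self.labels >= 1) & (self.labels <= 3)
        return self.labels == _LABELS[roi]

    @classmethod
    def from_geometry(
        cls,
        proj: ProjectionImage,
        neck_center_mm,
        neck_angle_deg: float,
        neck_box_width_mm: float,
        neck_box_length_mm: float,
        boundary_z_mm: float,
        mirrored: bool = False,
    ) -> "HipROISet":
        """Deterministic label map from explicit geometry (manual placement)."""
        dx, dz = proj.pixel_spacing_mm
        nx, nz = proj.mass_g.shape
        x = np.arange(nx)[:, None] * dx
        z = np.arange(nz)[None, :] * dz
        theta = np.radians(neck_angle_deg)
        a = np.array([np.cos(theta), np.sin(theta)])  # toward the head
        cx, cz = neck_center_mm
        s = (x - cx) * a[0] + (z - cz) * a[1]  # along-axis coordinate
        q = -(x - cx) * a[1] + (z - cz) * a[0]  # across-axis coordinate

        sil = proj.silhouette
        half_w = neck_box_width_mm / 2.0
        half_l = neck_box_length_mm / 2.0
        labels = np.zeros((nx, nz), dtype=np.int8)

        in_box = (np.abs(s) <= half_w) & (np.abs(q) <= half_l)
        head_side = s > half_w
        # most inferior z reached by a neck-box corner: the trochanter /
        # intertrochanter split line
        z_split = cz - half_w * abs(a[1]) - half_l * abs(a[0])

        above_boundary = z >= boundary_z_mm
        labels[sil & in_box & above_boundary] = _LABELS["neck"]
        rest = sil & above_boundary & ~in_box & ~head_side
        labels[rest & (z >= z_split)] = _LABELS["trochanter"]
        labels[rest & (z < z_split)] = _LABELS["intertrochanter"]
        labels[sil & head_side & (labels == 0)] = _LABELS["head"]
        return cls(
            labels, proj.pixel_spacing_mm, tuple(neck_center_mm),
            float(neck_angle_deg), float(neck_box_width_mm),
            float(neck_box_length_mm), float(boundary_z_mm), mirrored,
        )


def _chord_width(sil, spacing, point, direction, max_half=45.0, step=0.25):
    """Total silhouette length cut by the line through ``point`` along
    ``direction``; inf if the point itself is outside.  Using the full
    intersection (not just the run containing the point) penalises cuts that
    clip the head or trochanter, so the minimum lands across the neck."""
    nx, nz = sil.shape
    ss = np.arange(-max_half, max_half + step, step)
    px = point[0] + ss * direction[0]
    pz = point[1] + ss * direction[1]
    ix = np.round(px / spacing[0]).astype(int)
    iz = np.round(pz / spacing[1]).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iz >= 0) & (iz < nz)
    inside = np.zeros(ss.size, dtype=bool)
    inside[ok] = sil[ix[ok], iz[ok]]
    if not inside[ss.size // 2]:
        return np.inf
    return float(inside.sum()) * step


def _bottleneck_point(sil, edt, start, goal):
    """Pixel of minimal clearance on the maximum-bottleneck path start->goal.

    Dijkstra variant maximising the smallest EDT value met along the path
    (8-connected).  The returned pixel is the centre of the narrowest
    passage; when the clearance plateaus (a cylindrical neck), the median
    pixel of the plateau is returned so the centre sits mid-neck.
    """
    import heapq

    nx, nz = sil.shape
    best = {}
    parent = {}
    s = (int(start[0]), int(start[1]))
    g = (int(goal[0]), int(goal[1]))
    best[s] = (-edt[s], 0.0)
    heap = [((-edt[s], 0.0), s)]
    while heap:
        key, (i, k) = heapq.heappop(heap)
        if (i, k) == g:
            break
        if key > best[(i, k)]:
            continue
        neg_c, length = key
        for di in (-1, 0, 1):
            for dk in (-1, 0, 1):
                ni, nk = i + di, k + dk
                if 0 <= ni < nx and 0 <= nk < nz and sil[ni, nk]:
                    # maximise the bottleneck clearance; break ties by the
                    # shortest path so it runs down the middle, not along an
                    # equal-clearance annulus
                    cand = (max(neg_c, -edt[ni, nk]),
                            length + np.hypot(di, dk))
                    if (ni, nk) not in best or cand < best[(ni, nk)]:
                        best[(ni, nk)] = cand
                        parent[(ni, nk)] = (i, k)
                        heapq.heappush(heap, (cand, (ni, nk)))
    if g not in best:
        raise LandmarkError("head and distal shaft are not connected")
    path = [g]
    while path[-1] != s:
        path.append(parent[path[-1]])
    path = np.asarray(path[::-1])
    clearances = edt[path[:, 0], path[:, 1]]
    floor = clearances.min()
    plateau = np.nonzero(clearances <= floor * 1.05)[0]
    return tuple(path[int(np.median(plateau))])


def auto_place_rois(
    proj: ProjectionImage,
    neck_box_width_mm: float = 15.0,
    mirror: bool = False,
    min_silhouette_px: int = 500,
) -> HipROISet:
    """Locate the hip landmarks and build the standard ROI set.

    The femoral head is the centre of the largest circle inscribed in the
    medial lobe of the silhouette; the neck axis and centre jointly minimise
    the silhouette chord width among cuts through lines radiating from the
    head centre; the inferior boundary is where the medial silhouette edge
    rejoins the straight shaft below the lesser-trochanter prominence.
    ``mirror`` analyses a right femur by flipping left-right first.
    """
    sil = proj.silhouette
    if mirror:
        sil = sil[::-1, :]
    dx, dz = proj.pixel_spacing_mm
    n_sil = int(sil.sum())
    if n_sil < min_silhouette_px:
        raise LandmarkError(f"silhouette has {n_sil} px (<{min_silhouette_px})")
    _, n_comp = ndimage.label(sil, structure=np.ones((3, 3)))
    if n_comp != 1:
        raise LandmarkError(f"silhouette is disconnected ({n_comp} components)")

    xi, zi = np.nonzero(sil)
    centroid = np.array([xi.mean() * dx, zi.mean() * dz])

    # head = largest inscribed circle on the medial (+x) side
    edt = ndimage.distance_transform_edt(sil, sampling=(dx, dz))
    medial = (np.arange(sil.shape[0])[:, None] * dx >= centroid[0]).astype(float)
    hi, hk = np.unravel_index(np.argmax(edt * medial), sil.shape)
    head_center = np.array([hi * dx, hk * dz])
    r_head = float(edt[hi, hk])
    if r_head < 2 * max(dx, dz):
        raise LandmarkError("no inscribed head circle found")

    # neck centre: the bottleneck of the widest path from the head to the
    # distal shaft through the silhouette - the narrowest passage the femur
    # offers between its two massive ends
    distal_rows = zi <= zi.min() + 0.25 * (zi.max() - zi.min())
    if not distal_rows.any():
        raise LandmarkError("no distal shaft below the head")
    edt_distal = np.where(
        np.isin(np.arange(sil.shape[1]), np.unique(zi[distal_rows]))[None, :], edt, 0.0
    )
    si, sk = np.unravel_index(np.argmax(edt_distal), sil.shape)
    p_isthmus = _bottleneck_point(sil, edt, (hi, hk), (si, sk))
    neck_center0 = np.array([p_isthmus[0] * dx, p_isthmus[1] * dz])

    # neck axis: the head centre lies on the anatomical neck axis, and the
    # bottleneck of the head-shaft passage straddles it, so the line joining
    # them is the axis; the box centre is then the middle of the plateau of
    # near-minimal silhouette cuts along that line
    seg = neck_center0 - head_center
    if np.linalg.norm(seg) < 1e-6:
        raise LandmarkError("isthmus coincides with the head centre")
    ang_star = np.degrees(np.arctan2(seg[1], seg[0]))
    rad = np.radians(ang_star)
    a = np.array([np.cos(rad), np.sin(rad)])
    perp = np.array([-a[1], a[0]])
    ts = np.arange(0.9 * r_head, 2.5 * r_head, 0.5)
    widths = np.full(ts.size, np.inf)
    for j, t in enumerate(ts):
        p = head_center + t * a
        ix, iz = int(round(p[0] / dx)), int(round(p[1] / dz))
        if 0 <= ix < sil.shape[0] and 0 <= iz < sil.shape[1] \
                and edt[ix, iz] >= 3.0:
            widths[j] = _chord_width(sil, (dx, dz), p, perp)
    if not np.isfinite(widths).any():
        raise LandmarkError("no isthmus cut found along the neck axis")
    min_width = float(widths.min())
    plateau = np.nonzero(widths <= min_width * 1.05)[0]
    t_star = float(ts[int(np.median(plateau))])
    neck_center = head_center + t_star * a
    neck_angle = (ang_star + 180.0) % 360.0  # report axis pointing at the head
    if neck_angle > 180.0:
        neck_angle -= 360.0
    neck_length = min_width + 6.0  # span the full neck with margin

    boundary_z = _inferior_boundary(sil, (dx, dz), neck_center, neck_angle,
                                    neck_box_width_mm, neck_length)

    work = ProjectionImage(
        np.where(sil, 1.0, 0.0), np.where(sil, 1.0, 0.0), proj.pixel_spacing_mm
    ) if mirror else proj
    rois = HipROISet.from_geometry(
        work, neck_center, neck_angle, neck_box_width_mm, neck_length,
        boundary_z, mirrored=mirror,
    )
    if mirror:
        rois.labels = rois.labels[::-1, :]
    return rois


def _inferior_boundary(sil, spacing, neck_center, neck_angle, width, length):
    """z (mm) of the lower junction of the lesser trochanter and the shaft."""
    dx, dz = spacing
    theta = np.radians(neck_angle)
    z_split = neck_center[1] - (width / 2) * abs(np.sin(theta)) \
        - (length / 2) * abs(np.cos(theta))
    zi_all = np.nonzero(sil.any(axis=0))[0]
    z_bottom = zi_all.min() * dz
    k_hi = max(int(np.floor((z_split - 5.0) / dz)), 0)
    k_lo = int(np.ceil(z_bottom / dz))
    if k_hi - k_lo < 4:
        return z_bottom + 0.25 * (z_split - z_bottom)
    # medial silhouette edge per row, lightly smoothed
    x_med = np.full(sil.shape[1], np.nan)
    for k in range(k_lo, k_hi + 1):
        cols = np.nonzero(sil[:, k])[0]
        if cols.size:
            x_med[k] = cols.max() * dx
    ks = np.arange(k_lo, k_hi + 1)
    prof = x_med[ks]
    ok = np.isfinite(prof)
    if ok.sum() < 4:
        return z_bottom + 0.25 * (z_split - z_bottom)
    prof = np.interp(ks, ks[ok], prof[ok])
    kernel = np.ones(3) / 3.0
    prof_s = np.convolve(prof, kernel, mode="same")
    # straight-shaft reference from the lowest quarter of rows
    n_ref = max(len(prof_s) // 4, 2)
    shaft_ref = np.median(prof_s[:n_ref])
    bump = prof_s > shaft_ref + 2.0
    if not bump.any():
        return z_bottom + 0.25 * (z_split - z_bottom)
    i_bump_lo = np.nonzero(bump)[0][0]  # lowest-z row of the prominence
    # walk down from the bump to where the edge has rejoined the shaft
    below = np.nonzero(prof_s[:i_bump_lo] <= shaft_ref + 0.5)[0]
    if below.size == 0:
        return float(z_bottom)
    return float(ks[below.max()] * dz)


def measure_roi(
    proj: ProjectionImage,
    roi_pixels: np.ndarray,
    roi: str = "roi",
    compartment: str = "integral",
    allow_empty: bool = False,
) -> ROIResult:
    """Sum mass, pixel area and bone path volume over the ROI pixels."""
    roi_pixels = np.asarray(roi_pixels, dtype=bool)
    if roi_pixels.shape != proj.mass_g.shape:
        raise ValueError("ROI pixel map shape does not match the projection")
    n = int(roi_pixels.sum())
    if n == 0:
        if allow_empty:
            return ROIResult(roi, compartment, 0.0, 0.0, 0.0)
        raise UndefinedMeasureError(f"ROI '{roi}' contains no pixels")
    return ROIResult(
        roi=roi,
        compartment=compartment,
        mass_g=float(proj.mass_g[roi_pixels].sum()),
        area_cm2=n * proj.pixel_area_cm2,
        volume_cm3=float(proj.volume_cm3[roi_pixels].sum()),
    )


@dataclass
class CompartmentSplit:
    """Cortical/trabecular voxel masks and the per-ROI measurement table."""

    cortical_mask: np.ndarray
    trabecular_mask: np.ndarray
    params: CompartmentParams
    results: dict = field(default_factory=dict)  # roi -> compartment -> ROIResult

    def cortical_fraction(self, roi: str) -> float:
        integral = self.results[roi]["integral"].mass_g
        return self.results[roi]["cortical"].mass_g / integral if integral else 0.0


def split_compartments(
    ov: OrientedBoneVolume,
    rois: HipROISet | None = None,
    params: CompartmentParams = CompartmentParams(),
) -> CompartmentSplit:
    """Threshold voxels into cortical/trabecular and re-measure every ROI.

    A bone voxel is cortical iff its density >= the threshold.  The two
    compartment volumes are re-projected and measured through the same ROI
    pixel labels, so per-ROI cortical + trabecular mass and volume equal the
    integral values exactly.
    """
    density = np.nan_to_num(ov.density)
    cortical = ov.mask & (density >= params.cortical_threshold)
    trabecular = ov.mask & ~cortical
    split = CompartmentSplit(cortical, trabecular, params)
    if rois is None:
        return split

    projections = {
        "integral": project_coronal(ov),
        "cortical": project_coronal(ov.with_mask(cortical)),
        "trabecular": project_coronal(ov.with_mask(trabecular)),
    }
    for roi in ROI_NAMES:
        base = rois.pixels(roi)
        split.results[roi] = {}
        for comp, proj in projections.items():
            px = base if comp == "integral" else base & proj.silhouette
            split.results[roi][comp] = measure_roi(
                proj, px, roi, comp, allow_empty=True
            )
    return split
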