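"""HU -> equivalent K2HPO4 density calibration from an in-scan rod phantom.

The scanner is calibrated per study from rods of known equivalent aqueous
K2HPO4 density lying in the field of view.  Mean HU inside each rod is
regressed (ordinary least squares) against the nominal densities; the QA
reference rod (200.0 mg/cm3 nominal) additionally yields a multiplicative
beam-hardening correction to the slope, reported by :func:`qa_check` and
applied only when the user opts in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateFitError, GeometryError
from .volume import CalibratedVolume, CTVolume

#: nominal density of the QA reference solution, mg/cm3 (certified +-0.4)
QA_REFERENCE_DENSITY = 200.0

#: rod mean HU is sampled over a disk eroded to this fraction of the nominal
#: radius, to keep partial-volume rims out of the average
ROD_EROSION_FRACTION = 0.7


@dataclass(frozen=True)
class Rod:
    """One calibration rod: in-plane centre (mm), radius (mm), nominal density."""

    center_xy_mm: tuple[float, float]
    radius_mm: float
    density: float  # mg/cm3 equivalent K2HPO4

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("rod radius must be positive")


@dataclass(frozen=True)
class RodLayout:
    """Rod geometry plus the half-open axial slice range where rods are visible."""

    rods: tuple[Rod, ...]
    slice_range: tuple[int, int]

    def __post_init__(self):
        object.__setattr__(self, "rods", tuple(self.rods))
        if len(self.rods) < 2:
            raise ValueError("a rod layout needs at least two rods")
        lo, hi = self.slice_range
        if hi <= lo:
            raise ValueError("slice_range must be a non-empty half-open interval")

    @property
    def densities(self) -> np.ndarray:
        return np.array([r.density for r in self.rods])

    def reference_rod(self, nominal: float = QA_REFERENCE_DENSITY) -> Rod:
        """The rod whose nominal density is closest to the QA reference."""
        return min(self.rods, key=lambda r: abs(r.density - nominal))


@dataclass
class CalibrationFit:
    """Linear HU -> mg/cm3 mapping with optional beam-hardening slope factor."""

    slope: float  # mg/cm3 per HU
    intercept: float  # mg/cm3
    residuals: np.ndarray  # per-rod, mg/cm3
    rod_mean_hu: np.ndarray
    beam_hardening_factor: float = 1.0

    def __post_init__(self):
        if self.slope <= 0:
            raise DegenerateFitError(f"calibration slope must be positive, got {self.slope}")
        if self.beam_hardening_factor <= 0:
            raise ValueError("beam_hardening_factor must be positive")
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.rod_mean_hu = np.asarray(self.rod_mean_hu, dtype=float)

    def with_beam_hardening(self, factor: float) -> "CalibrationFit":
        return replace(self, beam_hardening_factor=float(factor))

    def density(self, hu):
        """Map HU to equivalent density with the correction applied."""
        return (self.slope * self.beam_hardening_factor) * np.asarray(hu) + self.intercept


@dataclass
class QAResult:
    measured_reference_density: float  # mg/cm3
    nominal_reference_density: float = QA_REFERENCE_DENSITY
    tolerance_percent: float = 2.0

    @property
    def percent_deviation(self) -> float:
        return 100.0 * (
            self.measured_reference_density - self.nominal_reference_density
        ) / self.nominal_reference_density

    @property
    def passed(self) -> bool:
        return abs(self.percent_deviation) <= self.tolerance_percent

    @property
    def suggested_beam_hardening_factor(self) -> float:
        """Slope factor that would map the measured reference onto nominal.

        Reported only; the caller decides whether to apply it via
        :meth:`CalibrationFit.with_beam_hardening`.
        """
        return self.nominal_reference_density / self.measured_reference_density

    def as_dict(self) -> dict:
        return {
            "measured_reference_density": self.measured_reference_density,
            "nominal_reference_density": self.nominal_reference_density,
            "percent_deviation": self.percent_deviation,
            "tolerance_percent": self.tolerance_percent,
            "pass": self.passed,
            "suggested_beam_hardening_factor": self.suggested_beam_hardening_factor,
        }


def _rod_disk_mask(volume, rod: Rod, erode: float = ROD_EROSION_FRACTION) -> np.ndarray:
    """In-plane boolean disk of the eroded rod on the volume's (x, y) lattice."""
    dx, dy, _ = volume.spacing
    nx, ny, _ = volume.shape
    cx, cy = rod.center_xy_mm
    r = rod.radius_mm * erode
    if not (0 <= cx - rod.radius_mm and cx + rod.radius_mm <= (nx - 1) * dx
            and 0 <= cy - rod.radius_mm and cy + rod.radius_mm <= (ny - 1) * dy):
        raise GeometryError(
            f"rod at ({cx}, {cy}) mm radius {rod.radius_mm} mm extends outside the grid"
        )
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    disk = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2 <= r**2
    if not disk.any():
        raise GeometryError(f"eroded rod disk at ({cx}, {cy}) mm covers no voxel centre")
    return disk


def rod_mean_value(volume, layout: RodLayout, rod: Rod) -> float:
    """Mean grid value over the eroded rod disk, averaged across the slice range."""
    lo, hi = layout.slice_range
    if not (0 <= lo < hi <= volume.shape[2]):
        raise GeometryError(
            f"rod slice range [{lo}, {hi}) outside the {volume.shape[2]}-slice grid"
        )
    disk = _rod_disk_mask(volume, rod)
    return float(volume.values[:, :, lo:hi][disk, :].mean())


def fit_calibration(volume: CTVolume, layout: RodLayout) -> CalibrationFit:
    """Ordinary least-squares line mapping mean rod HU to nominal density.

    Unweighted OLS over all rods; residuals are reported per rod in mg/cm3.
    The beam-hardening factor starts at 1.0 (no correction).
    """
    densities = layout.densities
    if np.unique(densities).size < 2:
        raise DegenerateFitError("need rods of at least two distinct nominal densities")
    mean_hu = np.array([rod_mean_value(volume, layout, rod) for rod in layout.rods])
    if np.ptp(mean_hu) == 0:
        raise DegenerateFitError("rod mean HU values are identical; cannot fit a line")
    slope, intercept = np.polyfit(mean_hu, densities, 1)
    residuals = densities - (slope * mean_hu + intercept)
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        residuals=residuals,
        rod_mean_hu=mean_hu,
    )


def apply_calibration(volume: CTVolume, fit: CalibrationFit) -> CalibratedVolume:
    """Elementwise affine map to equivalent density; spacing preserved."""
    return CalibratedVolume(fit.density(volume.values), volume.spacing)


def qa_check(
    qa_volume: CTVolume,
    layout: RodLayout,
    fit: CalibrationFit,
    nominal: float = QA_REFERENCE_DENSITY,
    tolerance_percent: float = 2.0,
) -> QAResult:
    """Measure the QA reference rod through the fit and report the deviation."""
    rod = layout.reference_rod(nominal)
    measured_hu = rod_mean_value(qa_volume, layout, rod)
    measured = float(fit.density(measured_hu))
    return QAResult(
        measured_reference_density=measured,
        nominal_reference_density=nominal,
        tolerance_percent=tolerance_percent,
    )
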