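"""File I/O, configuration and the end-to-end analysis driver.

Supported inputs: DICOM series directories (axial CT), NIfTI (.nii/.nii.gz)
and NRRD files.  All coordinates are reported in mm with 0-based,
voxel-centred indices and half-open intervals; axial slices are normalised
to z increasing inferior to superior.  CSV output is UTF-8 with a header
row and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (QA_REFERENCE_DENSITY, CalibrationFit, RodLayout,
                          apply_calibration, fit_calibration, qa_check)
from .errors import CTXAError, FormatError
from .orientation import apply_rotation, estimate_standard_rotation
from .projection import project_coronal
from .roi_analysis import (ROI_NAMES, CompartmentParams, HipROISet,
                           auto_place_rois, split_compartments)
from .segmentation import (SegmentationParams, fill_cortical_envelope,
                           segment_bone)
from .volume import CTVolume, VoxelBox

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers / writers

def read_ct_volume(path) -> CTVolume:
    """Read a CT volume in HU from a DICOM series directory, NIfTI or NRRD."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith(".nrrd"):
        return _read_nrrd(path)
    raise FormatError(f"unrecognised CT input: {path}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data, spacing)


def _read_nrrd(path: Path) -> CTVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NRRD, got {data.ndim}D")
    return CTVolume(np.transpose(data, (2, 1, 0)), tuple(img.GetSpacing()))


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir()
                   if p.is_file() and not p.name.startswith("."))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"{path}: no DICOM images found")

    iops = {tuple(np.round(np.asarray(ds.ImageOrientationPatient, float), 4))
            for ds in slices if "ImageOrientationPatient" in ds}
    if len(iops) > 1:
        raise FormatError(f"{path}: mixed slice orientations {sorted(iops)}")

    def z_of(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))

    slices.sort(key=z_of)  # z increasing: inferior -> superior
    zs = np.array([z_of(ds) for ds in slices])
    if len(zs) < 2:
        raise FormatError(f"{path}: a series needs at least two slices")
    steps = np.diff(zs)
    if np.any(steps <= 0):
        raise FormatError(f"{path}: duplicate slice positions")
    dz = np.median(steps)
    bad = np.nonzero(np.abs(steps - dz) > 0.01 * dz)[0]
    if bad.size:
        gaps = ", ".join(f"{zs[i]:.2f}->{zs[i+1]:.2f} mm" for i in bad[:3])
        raise FormatError(
            f"{path}: slice spacing deviates >1% from {dz:.3f} mm at {gaps}"
        )

    first = slices[0]
    if "PixelSpacing" not in first:
        raise FormatError(f"{path}: missing PixelSpacing tag")
    dy, dx = (float(v) for v in first.PixelSpacing)  # row, column spacing

    def hu(ds):
        arr = ds.pixel_array.astype(float)
        return arr * float(getattr(ds, "RescaleSlope", 1.0)) \
            + float(getattr(ds, "RescaleIntercept", 0.0))

    stack = np.stack([hu(ds) for ds in slices], axis=-1)  # (rows=y, cols=x, z)
    return CTVolume(np.transpose(stack, (1, 0, 2)), (dx, dy, float(dz)))


def write_nifti(grid, path) -> None:
    """Write any grid container (values + spacing) as NIfTI."""
    import nibabel as nib

    values = np.asarray(grid.values)
    if values.dtype == bool:
        values = values.astype(np.uint8)
    affine = np.diag(list(grid.spacing) + [1.0])
    nib.save(nib.Nifti1Image(values, affine), str(path))


def write_dicom_series(volume: CTVolume, directory) -> None:
    """Write an axial CT DICOM series (one file per slice)."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    dx, dy, dz = volume.spacing
    data = np.asarray(np.round(volume.values), dtype=np.int16)

    for k in range(volume.shape[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.Rows, ds.Columns = data.shape[1], data.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()
        ds.save_as(str(directory / f"slice_{k:04d}.dcm"), enforce_file_format=True)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class AnalysisConfig:
    """Everything :func:`run_analysis` needs; defaults are the clinical ones.

    Density thresholds (mg/cm3): segmentation floor -250, seed 120,
    neighbourhood 5 voxels, cortical/trabecular split 350; QA reference
    200.0 mg/cm3.
    """

    input_path: str = ""
    output_dir: str = "ctxa_output"
    rod_layout: RodLayout | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    compartments: CompartmentParams = field(default_factory=CompartmentParams)
    qa_reference_density: float = QA_REFERENCE_DENSITY
    qa_tolerance_percent: float = 2.0
    apply_beam_hardening: bool = False
    box_mm: tuple | None = None  # ((x0,x1),(y0,y1),(z0,z1)) half-open, mm
    # operator overrides
    neck_angle_deg: float | None = None
    neck_center_mm: tuple | None = None
    neck_box_width_mm: float = 15.0
    boundary_z_mm: float | None = None
    mirror: bool = False
    iso_spacing_mm: float | None = None
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rod_layout" in raw and raw["rod_layout"] is not None:
            raw["rod_layout"] = rod_layout_from_dict(raw["rod_layout"])
        if "segmentation" in raw and isinstance(raw["segmentation"], dict):
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        if "compartments" in raw and isinstance(raw["compartments"], dict):
            raw["compartments"] = CompartmentParams(**raw["compartments"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj
        return conv(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def rod_layout_from_dict(d: dict) -> RodLayout:
    from .calibration import Rod

    rods = tuple(
        Rod(tuple(r["center_xy_mm"]), r["radius_mm"], r["density"])
        for r in d["rods"]
    )
    return RodLayout(rods, tuple(d["slice_range"]))


# ---------------------------------------------------------------------------
# end-to-end pipeline

def run_analysis(config: AnalysisConfig, volume: CTVolume | None = None) -> dict:
    """Calibrate, segment, orient, project and measure; write the report.

    Returns a dict with the results table (pandas DataFrame under
    ``"table"``), the QA summary and the output paths.  Deterministic for a
    fixed config and input.  Stage failures are re-raised with the stage
    name and a remediation hint.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, hint, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CTXAError as err:
            raise type(err)(f"[{name}] {err}  (hint: {hint})") from err

    if volume is None:
        volume = stage("read", "check the input path and format",
                       read_ct_volume, config.input_path)

    qa_summary = None
    if config.rod_layout is not None:
        fit = stage("calibrate", "check rod layout coordinates and slice range",
                    fit_calibration, volume, config.rod_layout)
        qa = stage("qa", "check the reference rod position", qa_check,
                   volume, config.rod_layout, fit,
                   config.qa_reference_density, config.qa_tolerance_percent)
        qa_summary = qa.as_dict()
        if config.apply_beam_hardening:
            fit = fit.with_beam_hardening(qa.suggested_beam_hardening_factor)
        calibrated = apply_calibration(volume, fit)
    else:
        log.info("no rod layout: input treated as already calibrated (mg/cm3)")
        fit = None
        from .volume import CalibratedVolume
        calibrated = CalibratedVolume(volume.values, volume.spacing)

    box = None
    if config.box_mm is not None:
        lo = [b[0] for b in config.box_mm]
        hi = [b[1] for b in config.box_mm]
        box = VoxelBox.from_mm(lo, hi, volume.spacing)

    mask = stage("segment", "adjust thresholds or the analysis box",
                 segment_bone, calibrated, box, config.segmentation)
    mask = stage("segment", "adjust the analysis box",
                 fill_cortical_envelope, mask, box)
    rot = stage("orient", "supply manual shaft/neck angles",
                estimate_standard_rotation, mask)
    oriented = stage("orient", "reduce the grid or raise the memory bound",
                     apply_rotation, calibrated, mask, rot,
                     config.iso_spacing_mm)
    proj = stage("project", "check the oriented volume", project_coronal, oriented)

    rois = stage("roi", "place ROIs manually via overrides",
                 auto_place_rois, proj, config.neck_box_width_mm, config.mirror)
    if (config.neck_angle_deg is not None or config.neck_center_mm is not None
            or config.boundary_z_mm is not None):
        rois = HipROISet.from_geometry(
            proj,
            config.neck_center_mm or rois.neck_center_mm,
            config.neck_angle_deg if config.neck_angle_deg is not None
            else rois.neck_angle_deg,
            config.neck_box_width_mm,
            rois.neck_box_length_mm,
            config.boundary_z_mm if config.boundary_z_mm is not None
            else rois.boundary_z_mm,
            mirrored=rois.mirrored,
        )
    split = stage("compartments", "check the cortical threshold",
                  split_compartments, oriented, rois, config.compartments)

    rows = [split.results[roi][comp].as_dict()
            for roi in ROI_NAMES for comp in ("integral", "cortical", "trabecular")]
    table = pd.DataFrame(rows)

    report = {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_jsonable(),
        "qa": qa_summary,
        "calibration": None if fit is None else {
            "slope": fit.slope, "intercept": fit.intercept,
            "beam_hardening_factor": fit.beam_hardening_factor,
            "residuals": fit.residuals.tolist(),
        },
        "roi_geometry": {
            "neck_center_mm": list(rois.neck_center_mm),
            "neck_angle_deg": rois.neck_angle_deg,
            "neck_box_width_mm": rois.neck_box_width_mm,
            "neck_box_length_mm": rois.neck_box_length_mm,
            "boundary_z_mm": rois.boundary_z_mm,
            "mirrored": rois.mirrored,
        },
        "results": rows,
    }
    csv_path = outdir / "results.csv"
    json_path = outdir / "results.json"
    png_path = outdir / "projection.png"
    table.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    _render_projection(proj, rois, png_path)
    (outdir / "analysis.log").write_text(
        f"ctxa {__version__}\nconfig_hash {config.config_hash()}\n"
        + json.dumps(config.to_jsonable(), indent=2, sort_keys=True) + "\n"
    )
    report.update(table=table, paths={
        "csv": str(csv_path), "json": str(json_path), "png": str(png_path),
    })
    return report


def _render_projection(proj, rois, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(proj.abmd_g_cm2.T, origin="lower", cmap="gray",
              extent=(0, proj.mass_g.shape[0] * proj.pixel_spacing_mm[0],
                      0, proj.mass_g.shape[1] * proj.pixel_spacing_mm[1]))
    colors = {"neck": "tab:red", "trochanter": "tab:blue",
              "intertrochanter": "tab:green"}
    dx, dz = rois.pixel_spacing_mm
    x = np.arange(rois.labels.shape[0]) * dx
    z = np.arange(rois.labels.shape[1]) * dz
    for roi, color in colors.items():
        px = rois.pixels(roi)
        if px.any():
            ax.contour(x, z, px.T.astype(float), levels=[0.5],
                       colors=color, linewidths=1.0)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_title("CTXA projection (aBMD, g/cm$^2$)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
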