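"""Shared fixtures: one zero-noise reference phantom run through the whole
pipeline once per session, plus its independent integration oracle."""

import numpy as np
import pytest

from ctxa import (DigitalFemurSpec, apply_calibration, apply_rotation,
                  auto_place_rois, estimate_standard_rotation,
                  fill_cortical_envelope, fit_calibration, generate_phantom,
                  project_coronal, segment_bone, split_compartments)
from ctxa.phantom_sim import oracle_projection


@pytest.fixture(scope="session")
def femur_spec():
    return DigitalFemurSpec(noise_sd_hu=0.0)


@pytest.fixture(scope="session")
def phantom(femur_spec):
    return generate_phantom(femur_spec)


@pytest.fixture(scope="session")
def pipeline(femur_spec, phantom):
    """Full pipeline products on the reference phantom."""
    fit = fit_calibration(phantom.hu, femur_spec.rod_layout)
    cal = apply_calibration(phantom.hu, fit)
    mask = fill_cortical_envelope(segment_bone(cal))
    rot = estimate_standard_rotation(mask)
    ov = apply_rotation(cal, mask, rot)
    proj = project_coronal(ov)
    rois = auto_place_rois(proj)
    split = split_compartments(ov, rois)
    return {
        "fit": fit, "cal": cal, "mask": mask, "rot": rot,
        "oriented": ov, "proj": proj, "rois": rois, "split": split,
    }


@pytest.fixture(scope="session")
def oracle_total(femur_spec):
    """Independent numeric-integration truth for the whole silhouette."""
    return oracle_projection(femur_spec, pitch_mm=0.4, y_pitch_mm=0.2)


@pytest.fixture(scope="session")
def oriented_frame_origin(pipeline):
    """mm offset mapping scanner coordinates into the oriented grid."""
    rot = pipeline["rot"]
    coords = pipeline["mask"].coordinates_mm()
    return rot.apply_points(coords).min(axis=0) - 3.0
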