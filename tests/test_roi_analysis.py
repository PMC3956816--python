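"""Hip ROI placement, measurement arithmetic and compartment splits."""

import numpy as np
import pytest

from ctxa import (CompartmentParams, HipROISet, OrientedBoneVolume,
                  ProjectionImage, RigidRotation, auto_place_rois, measure_roi,
                  project_coronal, split_compartments)
from ctxa.errors import LandmarkError, UndefinedMeasureError


def uniform_projection(abmd=1.0, shape=(40, 40), pixel_mm=1.0, path_cm=1.0):
    area = (pixel_mm / 10.0) ** 2
    mass = np.full(shape, abmd * area)
    volume = np.full(shape, path_cm * area)
    return ProjectionImage(mass, volume, (pixel_mm, pixel_mm))


class TestAutoPlaceROIs:
    def test_neck_recovery_on_phantom(self, femur_spec, pipeline,
                                      oriented_frame_origin):
        rois = pipeline["rois"]
        rot = pipeline["rot"]
        lo = oriented_frame_origin
        # generating neck axis mapped into the oriented image frame
        base = rot.apply_points(femur_spec.neck_base[None, :])[0] - lo
        head = rot.apply_points(femur_spec.head_center[None, :])[0] - lo
        axis = np.array([head[0] - base[0], head[2] - base[2]])
        axis /= np.linalg.norm(axis)
        true_angle = np.degrees(np.arctan2(axis[1], axis[0]))
        assert abs(rois.neck_angle_deg - true_angle) < 5.0
        # detected centre sits on the generating axis line, inside the neck
        c = np.array(rois.neck_center_mm)
        v = c - np.array([base[0], base[2]])
        t_along = v @ axis
        perp = np.linalg.norm(v - t_along * axis)
        assert perp < 5.0
        assert 0.0 < t_along < femur_spec.neck_length

    def test_mirrored_input_gives_identical_areas(self, pipeline):
        proj = pipeline["proj"]
        flipped = ProjectionImage(proj.mass_g[::-1].copy(),
                                  proj.volume_cm3[::-1].copy(),
                                  proj.pixel_spacing_mm)
        rois = pipeline["rois"]
        rois_m = auto_place_rois(flipped, mirror=True)
        for roi in ("neck", "trochanter", "intertrochanter", "total_hip"):
            assert rois_m.pixels(roi).sum() == rois.pixels(roi).sum()
        assert np.array_equal(rois_m.pixels("total_hip"),
                              rois.pixels("total_hip")[::-1])

    def test_blank_image_fails_landmarks(self):
        blank = ProjectionImage(np.zeros((50, 50)), np.zeros((50, 50)), (1.0, 1.0))
        with pytest.raises(LandmarkError):
            auto_place_rois(blank)

    def test_small_silhouette_fails_landmarks(self):
        proj = uniform_projection(shape=(15, 15))
        proj.mass_g[:5, :] = 0.0
        proj.volume_cm3[:5, :] = 0.0
        with pytest.raises(LandmarkError):
            auto_place_rois(proj)


class TestMeasureROI:
    def test_uniform_slab_closed_form(self):
        # rho = 1000 mg/cm3 through 1 cm of bone over a 10 cm2 ROI
        proj = uniform_projection(abmd=1.0, shape=(40, 40), path_cm=1.0)
        roi = np.zeros((40, 40), dtype=bool)
        roi[:25, :40] = True  # 1000 px of 0.01 cm2
        res = measure_roi(proj, roi, "slab")
        assert res.area_cm2 == pytest.approx(10.0)
        assert res.mass_g == pytest.approx(10.0)
        assert res.volume_cm3 == pytest.approx(10.0)
        assert res.abmd_g_cm2 == pytest.approx(1.0)
        assert res.vbmd_mg_cm3 == pytest.approx(1000.0)

    def test_total_hip_is_sum_of_parts(self, pipeline):
        split = pipeline["split"]
        for comp in ("integral", "cortical", "trabecular"):
            parts = [split.results[r][comp]
                     for r in ("neck", "trochanter", "intertrochanter")]
            tot = split.results["total_hip"][comp]
            assert tot.mass_g == pytest.approx(sum(p.mass_g for p in parts),
                                               rel=1e-12, abs=1e-15)
            assert tot.area_cm2 == pytest.approx(sum(p.area_cm2 for p in parts),
                                                 rel=1e-12)
            assert tot.volume_cm3 == pytest.approx(
                sum(p.volume_cm3 for p in parts), rel=1e-12)

    def test_against_per_pixel_oracle(self):
        rng = np.random.default_rng(9)
        mass = rng.uniform(0.0, 1e-3, (20, 20))
        volume = rng.uniform(0.0, 1e-2, (20, 20))
        proj = ProjectionImage(mass, volume, (0.781, 0.781))
        roi = rng.random((20, 20)) < 0.5
        res = measure_roi(proj, roi, "random")
        exp_mass = sum(mass[i, k] for i, k in zip(*np.nonzero(roi)))
        exp_vol = sum(volume[i, k] for i, k in zip(*np.nonzero(roi)))
        assert res.mass_g == pytest.approx(exp_mass, rel=1e-12)
        assert res.volume_cm3 == pytest.approx(exp_vol, rel=1e-12)
        assert res.area_cm2 == pytest.approx(roi.sum() * 0.0781**2, rel=1e-12)

    def test_empty_roi_is_an_error(self):
        proj = uniform_projection()
        with pytest.raises(UndefinedMeasureError):
            measure_roi(proj, np.zeros((40, 40), dtype=bool), "empty")


def make_ov(density, mask, spacing=1.0):
    return OrientedBoneVolume(np.where(mask, density, np.nan), mask,
                              spacing, RigidRotation.identity())


def full_roi_set(shape):
    labels = np.zeros(shape, dtype=np.int8)
    labels[:, : shape[1] // 2] = 3
    labels[:, shape[1] // 2:] = 1
    return HipROISet(labels, (1.0, 1.0), (0.0, 0.0), 45.0, 15.0, 30.0, 0.0)


class TestSplitCompartments:
    def test_all_cortical_when_everything_dense(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        ov = make_ov(np.full((6, 6, 6), 800.0), mask)
        split = split_compartments(ov, full_roi_set((6, 6)))
        assert not split.trabecular_mask.any()
        for roi in ("neck", "intertrochanter", "total_hip"):
            assert split.results[roi]["trabecular"].mass_g == 0.0
            assert split.cortical_fraction(roi) == pytest.approx(1.0)

    def test_tiny_threshold_marks_everything_cortical(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        ov = make_ov(np.full((4, 4, 4), 90.0), mask)
        split = split_compartments(ov, full_roi_set((4, 4)),
                                   CompartmentParams(cortical_threshold=1e-9))
        assert split.cortical_fraction("total_hip") == pytest.approx(1.0)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            CompartmentParams(cortical_threshold=0.0)

    def test_exact_compartment_conservation(self, pipeline):
        split = pipeline["split"]
        for roi in ("neck", "trochanter", "intertrochanter", "total_hip"):
            r = split.results[roi]
            assert r["cortical"].mass_g + r["trabecular"].mass_g == pytest.approx(
                r["integral"].mass_g, rel=1e-12)
            assert r["cortical"].volume_cm3 + r["trabecular"].volume_cm3 == \
                pytest.approx(r["integral"].volume_cm3, rel=1e-12)

    def test_cortical_fraction_monotone_in_threshold(self, pipeline):
        ov = pipeline["oriented"]
        rois = pipeline["rois"]
        fractions = [
            split_compartments(ov, rois, CompartmentParams(t)).cortical_fraction(
                "total_hip")
            for t in (200.0, 350.0, 500.0, 700.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_shell_core_fraction_matches_analytic(self, femur_spec, pipeline,
                                                  oracle_total):
        ov = pipeline["oriented"]
        split = split_compartments(ov)
        dens = np.nan_to_num(ov.density)
        cort = (dens * split.cortical_mask).sum()
        total = (dens * ov.mask).sum()
        assert cort / total == pytest.approx(oracle_total["cortical_fraction"],
                                             abs=0.03)
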