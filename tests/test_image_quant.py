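"""Zonation, segmentation and zonal measurements on phantoms with known truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, spearmanr

from canaliflow import image_quant as iq, synthetic as S
from tests.conftest import measure_mean_diameter_profile

VS = S.DEFAULT_VOXEL_SIZE
CV = (24, 32, 2)
PV = (24, 32, 517)


# -- zone assignment --------------------------------------------------

def test_landmark_and_midpoint_zones():
    labels, _ = iq.assign_zones([CV], CV, PV, 18)
    assert labels[0] == 1
    labels, _ = iq.assign_zones([PV], CV, PV, 18)
    assert labels[0] == 18
    mid = tuple((np.array(CV) + np.array(PV)) / 2)
    labels, _ = iq.assign_zones([mid], CV, PV, 18)
    assert labels[0] == int(np.ceil(18 / 2))
    labels, _ = iq.assign_zones([mid], CV, PV, 9)
    assert labels[0] == int(np.ceil(9 / 2))


def test_boundary_exclusion_flags():
    _, excluded = iq.assign_zones([CV], CV, PV, 18, exclude_boundary=True)
    assert excluded[0] and excluded[-1] and not excluded[1:-1].any()


def test_uniform_points_give_uniform_zone_occupancy():
    rng = np.random.default_rng(0)
    n, n_zones = 20000, 10
    coords = np.column_stack([
        np.full(n, 24.0), np.full(n, 32.0),
        rng.uniform(CV[2], PV[2], n)])
    labels, _ = iq.assign_zones(coords, CV, PV, n_zones)
    lo, hi = binom.ppf([0.0005, 0.9995], n, 1 / n_zones)
    counts = np.bincount(labels, minlength=n_zones + 1)[1:]
    assert np.all((counts >= lo) & (counts <= hi))


def test_coordinate_outside_stack_rejected():
    with pytest.raises(ValueError, match="outside"):
        iq.assign_zones([(100, 0, 0)], CV, PV, 18, stack_shape=(48, 64, 520))


@settings(derandomize=True, max_examples=50)
@given(st.floats(0.01, 0.99), st.integers(2, 20))
def test_mirrored_landmarks_reverse_zone_labels(p, n_zones):
    coord = np.array(CV) + p * (np.array(PV) - np.array(CV))
    fwd, _ = iq.assign_zones([coord], CV, PV, n_zones)
    rev, _ = iq.assign_zones([coord], PV, CV, n_zones)
    # away from exact bin edges the mirror is exact
    if abs((p * n_zones) % 1.0 - 0.0) > 1e-6:
        assert fwd[0] + rev[0] == n_zones + 1


# -- segmentation -----------------------------------------------------

def test_blank_stack_signals_no_structures():
    with pytest.raises(iq.NoStructuresError):
        iq.segment_bc(np.zeros((10, 10, 10)))


def test_inverted_contrast_flagged():
    rng = np.random.default_rng(1)
    img = 200.0 - 190.0 * (rng.uniform(size=(12, 12, 12)) < 0.1)
    with pytest.raises(iq.InvertedContrastError):
        iq.segment_bc(img)


def test_cylinder_mask_iou_against_truth(clean_phantom):
    spec, bc, _, _, truth = clean_phantom
    seg = iq.segment_bc(bc, voxel_size=spec.voxel_size)
    inter = (seg.mask & truth.bc_mask).sum()
    union = (seg.mask | truth.bc_mask).sum()
    assert inter / union >= 0.9


def test_diameter_invariant_under_intensity_rescaling(clean_phantom):
    spec, bc, _, _, _ = clean_phantom
    a = iq.segment_bc(bc, voxel_size=spec.voxel_size)
    b = iq.segment_bc(bc * 7.3, voxel_size=spec.voxel_size)
    pa = iq.measure_bc_diameter(a, spec.cv_landmark, spec.pv_landmark,
                                voxel_size=spec.voxel_size)
    pb = iq.measure_bc_diameter(b, spec.cv_landmark, spec.pv_landmark,
                                voxel_size=spec.voxel_size)
    assert np.allclose(pa.value, pb.value, equal_nan=True)


# -- diameter profiles ------------------------------------------------

def test_constant_diameter_phantom_recovered_within_half_voxel():
    diams = np.full(18, 2.0)
    mean, excluded = measure_mean_diameter_profile(diams, (0, 1, 2))
    assert np.nanmax(np.abs(mean - 2.0)[~excluded]) <= 0.15


def test_zonal_profile_recovered_within_tolerance(untreated_profile_mean):
    truth, measured, excluded = untreated_profile_mean
    err = np.abs(measured - truth)[~excluded]
    assert np.nanmax(err) <= 0.15


def test_rising_truth_gives_rising_measured_profile(untreated_profile_mean):
    truth, measured, excluded = untreated_profile_mean
    keep = ~excluded & np.isfinite(measured)
    rho = spearmanr(np.arange(18)[keep], measured[keep]).statistic
    assert rho > 0.8
    assert measured[keep][-1] > measured[keep][0]


def test_mirrored_stack_reverses_diameter_profile(clean_phantom):
    spec, bc, _, _, _ = clean_phantom
    seg = iq.segment_bc(bc, voxel_size=spec.voxel_size)
    fwd = iq.measure_bc_diameter(seg, spec.cv_landmark, spec.pv_landmark,
                                 voxel_size=spec.voxel_size)
    rev = iq.measure_bc_diameter(seg, spec.pv_landmark, spec.cv_landmark,
                                 voxel_size=spec.voxel_size)
    assert np.allclose(fwd.value, rev.value[::-1], equal_nan=True, atol=0.06)


def test_untreated_vs_post_ph_mean_increase_matches_truth():
    d0 = np.linspace(1.96, 2.27, 18)
    d1 = np.linspace(2.40, 2.61, 18)
    m0, exc = measure_mean_diameter_profile(d0, (0, 1, 2))
    m1, _ = measure_mean_diameter_profile(d1, (10, 11, 12))
    true_pct = 100.0 * np.mean(d1 / d0 - 1.0)
    meas_pct = 100.0 * np.nanmean((m1 / m0 - 1.0)[~exc])
    assert abs(meas_pct - true_pct) <= 3.0


# -- intensities ------------------------------------------------------

def test_uniform_nuclear_intensity_measured_exactly(clean_phantom):
    spec, _, nuc, _, _ = clean_phantom
    prof = iq.measure_nuclear_intensity(nuc, nuc, spec.cv_landmark,
                                        spec.pv_landmark,
                                        voxel_size=spec.voxel_size)
    ok = np.isfinite(prof.value)
    assert ok.sum() >= 8
    assert np.allclose(prof.value[ok], 100.0)
    assert np.allclose(prof.sem[ok], 0.0, atol=1e-9)


def test_zone_graded_nuclear_intensity_rank_correlates_with_truth():
    grad = np.linspace(80.0, 160.0, 10)
    spec = S.LobulePhantomSpec(seed=4, psf_sigma=0.0, background=0.0,
                               n_nuclei=80, zonal_nuclear_intensity=grad)
    _, nuc, _, truth = S.generate_lobule_stack(spec)
    prof = iq.measure_nuclear_intensity(nuc, nuc, spec.cv_landmark,
                                        spec.pv_landmark,
                                        voxel_size=spec.voxel_size)
    ok = np.isfinite(prof.value)
    rho = spearmanr(prof.value[ok], grad[ok]).statistic
    assert rho >= 0.9


def test_profile_normalized_to_baseline_is_unity(clean_phantom):
    spec, _, nuc, _, _ = clean_phantom
    prof = iq.measure_nuclear_intensity(nuc, nuc, spec.cv_landmark,
                                        spec.pv_landmark,
                                        voxel_size=spec.voxel_size)
    ratio = iq.normalize_profiles(prof, prof)
    ok = np.isfinite(ratio.value)
    assert np.allclose(ratio.value[ok], 1.0)


def test_apical_shell_intensity_and_offset_invariance(clean_phantom):
    spec, _, _, marker, truth = clean_phantom
    scalar, _ = iq.measure_apical_intensity(truth.bc_mask, marker,
                                            voxel_size=spec.voxel_size)
    assert scalar == pytest.approx(spec.apical_marker_level, rel=0.02)
    offset, _ = iq.measure_apical_intensity(truth.bc_mask, marker + 41.0,
                                            voxel_size=spec.voxel_size)
    assert offset == pytest.approx(scalar, abs=1.0)


def test_apical_ratio_between_conditions_survives_blur():
    base = S.LobulePhantomSpec(seed=6, apical_marker_level=100.0, n_nuclei=0,
                               stack_shape=(24, 40, 160))
    high = S.LobulePhantomSpec(seed=6, apical_marker_level=170.0, n_nuclei=0,
                               stack_shape=(24, 40, 160))
    _, _, mk0, tr0 = S.generate_lobule_stack(base)
    _, _, mk1, tr1 = S.generate_lobule_stack(high)
    s0, _ = iq.measure_apical_intensity(tr0.bc_mask, mk0,
                                        voxel_size=base.voxel_size)
    s1, _ = iq.measure_apical_intensity(tr1.bc_mask, mk1,
                                        voxel_size=base.voxel_size)
    assert s1 / s0 == pytest.approx(1.7, rel=0.10)


def test_empty_mask_signals(clean_phantom):
    spec, _, _, marker, _ = clean_phantom
    with pytest.raises(iq.NoStructuresError):
        iq.measure_apical_intensity(np.zeros_like(marker, dtype=bool),
                                    marker, voxel_size=spec.voxel_size)
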