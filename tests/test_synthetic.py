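"""Phantom generator, stimulus trajectory, YAP table and fixture plumbing."""

import json

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import ndimage as ndi

from canaliflow import hippo, synthetic as S
from canaliflow.fitting import row_stimuli


def small_spec(**kw):
    base = dict(stack_shape=(24, 40, 160), n_nuclei=10, psf_sigma=0.0,
                seed=0)
    base.update(kw)
    return S.LobulePhantomSpec(**base)


def test_identical_spec_and_seed_give_bit_identical_stacks():
    a = S.generate_lobule_stack(small_spec(shot_noise=1.0, read_noise=2.0))
    b = S.generate_lobule_stack(small_spec(shot_noise=1.0, read_noise=2.0))
    for x, y in zip(a[:3], b[:3]):
        assert np.array_equal(x, y)


def test_different_seeds_same_geometry_statistics():
    """Voxelwise different stacks whose recovered tube radius statistic
    agrees within 2% across 10 seeds (same nominal geometry)."""
    radii = []
    first = None
    for seed in range(10):
        spec = small_spec(seed=seed)
        bc, _, _, truth = S.generate_lobule_stack(spec)
        edt = ndi.distance_transform_edt(truth.bc_mask,
                                         sampling=spec.voxel_size)
        radii.append(np.median(edt[tuple(truth.centerline.T)]))
        if first is None:
            first = bc
        elif seed == 1:
            assert not np.array_equal(bc, first)
    radii = np.array(radii)
    assert np.max(np.abs(radii - radii.mean()) / radii.mean()) < 0.02


def test_constant_tube_radius_recovered_along_true_centerline():
    spec = small_spec(zonal_diameter=np.full(18, 2.0))
    _, _, _, truth = S.generate_lobule_stack(spec)
    edt = ndi.distance_transform_edt(truth.bc_mask,
                                     sampling=spec.voxel_size)
    r = edt[tuple(truth.centerline.T)]
    # median within half the largest voxel side; every sample within
    # half the voxel diagonal (centerline voxels are grid-quantized)
    assert abs(np.median(r) - 1.0) <= 0.15
    assert np.all(np.abs(r - 1.0) <= np.linalg.norm(spec.voxel_size) / 2)


def test_undersized_stack_rejected_with_sizing_message():
    with pytest.raises(ValueError, match="too small"):
        S.generate_lobule_stack(S.LobulePhantomSpec(
            stack_shape=(10, 10, 10), n_zones=18,
            cv_landmark=(5, 5, 1), pv_landmark=(5, 5, 8)))


def test_nuclei_do_not_overlap_tube_or_each_other():
    spec = small_spec(n_nuclei=15, stack_shape=(32, 48, 160))
    _, _, _, truth = S.generate_lobule_stack(spec)
    assert truth.nuclei_labels.max() > 0
    assert not np.any(truth.bc_mask & (truth.nuclei_labels > 0))


# -- stimulus trajectory ----------------------------------------------

def test_no_resection_means_unit_stimulus_everywhere():
    traj = S.generate_stimulus_trajectory(0.0, t_grid=np.array([0.5, 2, 5]))
    assert np.allclose(traj["stimulus"], 1.0)


def test_stimulus_returns_to_baseline_after_full_regrowth():
    traj = S.generate_stimulus_trajectory(0.68, t_grid=np.array([0.1, 50.0]))
    late = traj[traj.time_days == 50.0]["stimulus"]
    assert np.allclose(late, 1.0, atol=1e-3)


def test_early_stimulus_near_twofold_tension_rise():
    """At 0.8 days post-resection (f = 0.68) the mean zonal stimulus is
    around the predicted ~2-fold tension increase."""
    traj = S.generate_stimulus_trajectory(0.68, t_grid=np.array([0.8]))
    assert 1.7 <= traj["stimulus"].mean() <= 2.9


def test_mass_recovery_curve_shape():
    t = np.linspace(0, 12, 120)
    m = S.liver_mass_recovery(t, 0.68)
    assert m[0] == pytest.approx(0.32)
    assert np.all(np.diff(m) >= 0) and m[60] > m[0]
    assert m[-1] == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ValueError, match="increasing"):
        S.liver_mass_recovery(t, 0.68, steepness=-1.0)


# -- YAP measurement tables -------------------------------------------

def test_zero_noise_rows_equal_forward_model_exactly(ref_params,
                                                     stimulus_trajectory):
    spec = S.TimeCourseSpec(noise_cv=0.0,
                            stimulus_trajectory=stimulus_trajectory)
    ds = S.generate_yap_dataset(spec)
    stim = row_stimuli(ds, stimulus_trajectory)
    uniq, inv = np.unique(stim, return_inverse=True)
    nuc, tot = hippo.normalized_observables(ref_params, uniq)
    pred = np.where(ds.table["observable"] == "nuclear", nuc[inv], tot[inv])
    assert np.allclose(ds.table["value"], pred, rtol=1e-12)


def test_default_design_yields_120_points_two_observables_10_zones():
    ds = S.generate_yap_dataset(S.TimeCourseSpec())
    assert len(ds) == 120
    assert ds.observables == ("nuclear", "total")
    assert ds.table["zone"].max() == 10
    for obs in ds.observables:
        t0 = ds.table[(ds.table.time_days == 0)
                      & (ds.table.observable == obs)]
        assert t0["value"].mean() == pytest.approx(1.0)


def test_noisy_replicate_mean_within_monte_carlo_interval(ref_params):
    """100 replicates at one design point: the sample mean sits within
    3 standard errors of the forward-model value."""
    spec = S.TimeCourseSpec(time_points=(0.0, 1.5), zones=1, replicates=100,
                            noise_cv=0.1, n_points_target=400, seed=5,
                            stimulus_trajectory=pd.DataFrame(
                                {"time_days": [1.5], "zone": [1],
                                 "stimulus": [2.2]}))
    ds = S.generate_yap_dataset(spec)
    nuc_true, _ = hippo.normalized_observables(ref_params, np.array([2.2]))
    rows = ds.table[(ds.table.time_days == 1.5)
                    & (ds.table.observable == "nuclear")]["value"]
    # undo the division by the noisy t=0 mean so samples are iid
    t0 = ds.table[(ds.table.time_days == 0)
                  & (ds.table.observable == "nuclear")]["value"]
    undone = rows * t0.mean()
    sem = undone.std() / np.sqrt(len(undone))
    assert abs(undone.mean() - nuc_true[0]) < 3 * sem


def test_invalid_true_params_rejected():
    with pytest.raises(ValueError):
        S.TimeCourseSpec(noise_cv=-0.1)
    bad = hippo.HippoParams.reference()
    bad = bad.with_free([getattr(bad, n) * (0.05 if n == "V_inact" else 1.0)
                         for n in bad.free_names])
    with pytest.raises(ValueError, match="steady state"):
        S.generate_yap_dataset(S.TimeCourseSpec(true_params=bad))


# -- fixtures on disk -------------------------------------------------

def test_fixture_round_trip_and_checksums(tmp_path):
    import tifffile
    specs = {"ph": small_spec(n_nuclei=5),
             "tc": S.TimeCourseSpec(seed=2)}
    manifest = S.write_fixtures(tmp_path, specs)
    # round trip: written mask equals in-memory truth bit-exactly
    _, _, _, truth = S.generate_lobule_stack(specs["ph"])
    mask = tifffile.imread(tmp_path / "ph_bc_mask.tif")
    assert np.array_equal(mask.astype(bool), truth.bc_mask)
    assert S.verify_fixtures(tmp_path) == []
    # 1-byte corruption is detected
    target = tmp_path / "ph_truth.json"
    raw = bytearray(target.read_bytes())
    raw[10] ^= 0xFF
    target.write_bytes(bytes(raw))
    assert "ph_truth.json" in S.verify_fixtures(tmp_path)


def test_regeneration_reproduces_checksums(tmp_path):
    specs = {"tc": S.TimeCourseSpec(seed=9)}
    m1 = S.write_fixtures(tmp_path / "a", specs)
    m2 = S.write_fixtures(tmp_path / "b", specs)
    assert m1["files"] == m2["files"]


def test_ground_truth_dict_round_trip_is_lossless():
    _, _, _, truth = S.generate_lobule_stack(small_spec(n_nuclei=5))
    d = json.loads(json.dumps(truth.to_dict()))
    back = S.GroundTruth.from_dict(d)
    assert np.allclose(back.zonal_diameter, truth.zonal_diameter)
    assert np.array_equal(back.nucleus_zone, truth.nucleus_zone)
    assert np.array_equal(back.centerline, truth.centerline)
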