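"""Shared fixtures: reference model parameters and phantom measurements.

The expensive 3D phantoms are generated once per session; profile-truth
comparisons use means over three phantom replicates, mirroring the
replicate-animal design of the measurements they emulate.
"""

import numpy as np
import pytest

from canaliflow import hippo, image_quant as iq, synthetic as S


@pytest.fixture(scope="session")
def ref_params():
    return hippo.HippoParams.reference()


@pytest.fixture(scope="session")
def stimulus_trajectory():
    spec = S.TimeCourseSpec()
    times = np.asarray(spec.time_points)
    return S.generate_stimulus_trajectory(
        spec.resection_fraction, spec.regrowth_halftime,
        t_grid=times[times > 0])


def measure_mean_diameter_profile(diameters, seeds, n_zones=18):
    """Replicate-mean measured diameter profile on noise-free phantoms."""
    values = []
    for seed in seeds:
        spec = S.LobulePhantomSpec(seed=seed, psf_sigma=0.0, n_nuclei=0,
                                   zonal_diameter=diameters, n_zones=n_zones)
        bc, _, _, truth = S.generate_lobule_stack(spec)
        seg = iq.segment_bc(bc, voxel_size=spec.voxel_size)
        prof = iq.measure_bc_diameter(seg, spec.cv_landmark, spec.pv_landmark,
                                      n_zones=n_zones,
                                      voxel_size=spec.voxel_size)
        values.append(prof.value)
    return np.nanmean(values, axis=0), prof.excluded


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free, blur-free phantom with nuclei and ground truth."""
    spec = S.LobulePhantomSpec(seed=3, psf_sigma=0.0, background=0.0,
                               n_nuclei=80,
                               zonal_nuclear_intensity=np.full(10, 100.0))
    bc, nuc, marker, truth = S.generate_lobule_stack(spec)
    return spec, bc, nuc, marker, truth


@pytest.fixture(scope="session")
def untreated_profile_mean():
    diams = np.linspace(1.96, 2.27, 18)
    mean, excluded = measure_mean_diameter_profile(diams, (0, 1, 2))
    return diams, mean, excluded
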