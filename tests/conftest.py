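import numpy as np
import pytest

import memperm as mp


@pytest.fixture(scope="session")
def oxygen_spec():
    return mp.oxygen_like_spec()


@pytest.fixture(scope="session")
def geometry():
    return mp.MembraneGeometry(half_thickness=15.0, z_mid=4.0)


@pytest.fixture(scope="session")
def oxygen_trajs(oxygen_spec):
    """One moderately sampled oxygen-like run shared across tests."""
    run = mp.SyntheticRunSpec(profile=oxygen_spec, n_permeants=30,
                              t_total=10000.0, seed=11)
    return mp.simulate_permeants(run)


@pytest.fixture
def flat_spec():
    """Flat free energy, constant isotropic diffusion 0.3 Å²/ps."""
    return mp.ProfileSpec(H=70.0, f_coeffs=[0.0],
                          log_dperp_coeffs=[np.log(0.3)],
                          log_dpar_coeffs=[np.log(0.3)])


def make_traj(z_series, times=None, box=(40.0, 40.0, 70.0), xy=None,
              pid="p0", temperature=298.0):
    """Hand-built single-permeant trajectory for event fixtures."""
    z = np.asarray(z_series, dtype=float)
    t = np.arange(len(z), dtype=float) if times is None else np.asarray(times)
    if xy is None:
        xy = np.zeros((len(z), 2))
    xyz = np.column_stack([np.asarray(xy), z])
    return mp.PermeantTrajectory(permeant_id=pid, permeant_type="test",
                                 times=t, xyz=xyz, box=box,
                                 temperature=temperature)
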