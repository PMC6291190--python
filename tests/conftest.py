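import numpy as np
import pytest

from metacal import metad_reweight as mr
from metacal import synthetic as syn


@pytest.fixture(scope="session")
def dw_metad():
    """Well-tempered MetaD run on the 8 kT double well, with TP weights.

    Shared across reweighting tests; every-step recording so short-lag
    dynamical averages are resolvable.
    """
    pot = syn.DoubleWell1D(barrier=8.0)
    traj, hills = syn.metad_run(
        pot, syn.SimConfig(dt=0.005, n_steps=600_000, seed=0, stride=1),
        height=1.2, sigma=0.15, deposit_stride=500, bias_factor=12.0,
    )
    t = traj["time"].to_numpy()
    V = traj["bias"].to_numpy()
    c = mr.bias_correction_series(hills)(t)
    w = mr.frame_weights(V, c, 1.0, kB=1.0)
    return {
        "potential": pot,
        "traj": traj,
        "hills": hills,
        "bias": V,
        "correction": c,
        "weights": w,
    }


@pytest.fixture(scope="session")
def dw_unbiased():
    """Long unbiased run on the same double well (oracle for reweighting)."""
    pot = syn.DoubleWell1D(barrier=8.0)
    traj = syn.brownian_dynamics(
        pot, syn.SimConfig(dt=0.005, n_steps=2_000_000, seed=7, stride=1)
    )
    return traj


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
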