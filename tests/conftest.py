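import numpy as np
import pytest

from actomech import synthetic as syn


@pytest.fixture(scope="session")
def brownian_300():
    """Reference free-diffusion cohort: 300 trajectories, D = 0.01
    um^2/s, dt = 1 s, 600 steps."""
    return syn.gen_brownian(300, 600, 1.0, 0.01, seed=1)


@pytest.fixture(scope="session")
def piv_texture():
    """Well-textured random image for PIV checks."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(0)
    return gaussian_filter(rng.random((256, 256)), 1.0) * 100


@pytest.fixture(scope="session")
def small_network():
    """Small assembled branched network reused across simulator tests."""
    from actomech.abm import SimParams, assemble_network

    params = SimParams(
        c_actin=5.0, r_arp=0.01, domain=(1.5, 1.5, 0.75), n_seeds=6, seed=3
    )
    return params, assemble_network(params)
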