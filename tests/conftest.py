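import numpy as np
import pytest

from mccsd import MCParams, build_protocol, mc_signal


@pytest.fixture(scope="session")
def p3():
    return build_protocol("P3", directions_seed=0)


@pytest.fixture(scope="session")
def p1():
    return build_protocol("P1", directions_seed=0)


@pytest.fixture(scope="session")
def wm_params():
    """Single-fiber white-matter voxel: no isotropic bundle."""
    return MCParams(
        fb=0.0, fcsf=0.0, fr=0.6, lambda_iso=2.0e-9, lambda_par=1.7e-9,
        mu=np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture(scope="session")
def wm_signal(wm_params, p3):
    return mc_signal(wm_params, p3)
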