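"""Shared fixtures: default chain, seeded RNG and cached synthetic data.

Session-scoped fixtures cache the expensive artifacts (synthetic
sessions, fitted calibration) so independent tests can share them.
"""

import numpy as np
import pytest

from neckbrace.calibration import calibrate_session
from neckbrace.chain import default_chain
from neckbrace.synthetic import SyntheticSpec, generate_session


@pytest.fixture(scope="session")
def chain():
    return default_chain()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cal_session():
    """Calibration session at default noise (seed 10)."""
    return generate_session(SyntheticSpec(random_seed=10))


@pytest.fixture(scope="session")
def val_session():
    """Held-out validation session at default noise (seed 11)."""
    return generate_session(SyntheticSpec(random_seed=11))


@pytest.fixture(scope="session")
def fitted_model(chain, cal_session):
    return calibrate_session(
        cal_session.markers, cal_session.voltages, chain
    )


@pytest.fixture(scope="session")
def noiseless_session():
    spec = SyntheticSpec(
        random_seed=5, marker_noise_mm=0.0, voltage_noise_fraction_fs=0.0,
        cardiac_amplitude_mv=0.0, emg_baseline_mv=0.0,
    )
    return generate_session(spec)
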