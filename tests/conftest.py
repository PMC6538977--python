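import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes helpers importable

import neodepth as nd


@pytest.fixture(scope="session")
def neonatal_session():
    """One discontinuous 5-min neonatal session with a two-level ladder."""
    params = nd.NeonatalLfpParams(
        duration_s=300.0, seed=42, dose_response={0.0: 1.0, 2.0: 0.3}
    )
    rec, truth = nd.gen_neonatal_session(params, [(0.0, 0.0), (150.0, 2.0)])
    return params, rec, truth


@pytest.fixture(scope="session")
def infant_session():
    """Small 0-2-month infant EEG session (4 channels, 128 Hz, 22 min)."""
    params = nd.default_infant_params(
        "0-2",
        seed=7,
        n_channels=4,
        sampling_rate_hz=128.0,
        duration_min=22,
        concentration_profile=((0, 0.0), (5, 0.5), (10, 1.0), (16, 1.5)),
    )
    rec, truth = nd.gen_infant_session(params)
    return params, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
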