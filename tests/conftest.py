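import numpy as np
import pytest

from sul7d import BindingParameters
from sul7d.synthetic_data import (
    DEFAULT_P_TOTAL,
    NoiseModel,
    default_schedule,
    simulate_titration,
)


@pytest.fixture
def sac7d_like_truth() -> BindingParameters:
    """Parameters in the regime reported for Sac7d: K_D 13 uM, n 6.4, Q_max 0.9."""
    return BindingParameters.from_kd(13e-6, 6.4, 0.9)


@pytest.fixture
def noiseless_experiment(sac7d_like_truth):
    return simulate_titration(
        sac7d_like_truth,
        p_total=DEFAULT_P_TOTAL,
        schedule=default_schedule(sac7d_like_truth, DEFAULT_P_TOTAL),
        noise=NoiseModel(sigma_rel=0.0, seed=0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160701)
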