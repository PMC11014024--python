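import numpy as np
import pytest

from cosoft import BatchTensor, CampaignConfig, simulate_campaign


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tensor(rng):
    """A 4-batch x 3-variable x 6-time tensor with a half-labeled grid."""
    x = rng.normal(size=(4, 3, 6))
    y = rng.normal(size=(4, 6))
    mask = np.zeros((4, 6), dtype=bool)
    mask[:, ::2] = True
    return BatchTensor(x=x, y=y, mask=mask, variable_names=["a", "b", "c"])


@pytest.fixture
def tiny_campaign():
    """Small noisy campaign used by pipeline-level tests."""
    return simulate_campaign(
        CampaignConfig(n_batches=8, n_timepoints=30, seed=7)
    )


@pytest.fixture
def noiseless_campaign():
    """Deterministic campaign: no measurement noise, no setpoint jitter."""
    return simulate_campaign(
        CampaignConfig(n_batches=8, n_timepoints=30,
                       noise_sd=0.0, fluctuation_fraction=0.0, seed=7)
    )
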