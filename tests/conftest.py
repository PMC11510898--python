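import pytest

from salgae import SalinityResponseModel, SyntheticExperimentConfig


@pytest.fixture
def true_model():
    """Reference salinity-response model used across fitting tests."""
    return SalinityResponseModel(pmax=15.0, a=10.0, b=15.0, sopt=30.0)


@pytest.fixture
def noiseless_config(true_model):
    return SyntheticExperimentConfig(true_model=true_model, noise_sigma=0.0, seed=0)
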