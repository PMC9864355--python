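import pytest

from dgdis import DEFAULT_CONFIG, ModelConfig


@pytest.fixture
def default_config() -> ModelConfig:
    """Resting agreement defaults: bias 0, LoA 2 L/min, CO in [1.3, 10.2]."""
    return DEFAULT_CONFIG


@pytest.fixture
def untruncated_config() -> ModelConfig:
    """Same agreement parameters with the CO truncation pushed to infinity."""
    return ModelConfig(co_min=1e-9, co_max=1e9)
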