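import dataclasses

import pytest

from irct_cea import builtin_irct_config
from irct_cea.model_config import ModelConfig


@pytest.fixture(scope="session")
def base_config() -> ModelConfig:
    return builtin_irct_config()


def zero_probability_config(config: ModelConfig) -> ModelConfig:
    """Copy of a config with all event probabilities set to zero."""
    strategies = tuple(
        dataclasses.replace(s, p_reoperation=0.0, p_conversion=0.0)
        for s in config.strategies)
    return dataclasses.replace(config, strategies=strategies)


def with_settings(config: ModelConfig, **kwargs) -> ModelConfig:
    return dataclasses.replace(
        config, settings=dataclasses.replace(config.settings, **kwargs))
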