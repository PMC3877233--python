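import pytest

from benthox import (
    ClimatologyConfig,
    ModelParameters,
    SigmoidParams,
    build_synthetic_climatology,
    default_sigmoid,
)


@pytest.fixture(scope="session")
def forcing():
    """Deterministic default climatology (no noise)."""
    return build_synthetic_climatology(ClimatologyConfig(), seed=1)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def sigmoid():
    return default_sigmoid()
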