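import numpy as np
import pytest

from mscs_erasure import (
    ChannelParams,
    default_params,
    midpoint_tension,
    make_erasure_ramp,
)


@pytest.fixture(scope="session")
def params() -> ChannelParams:
    return default_params()


@pytest.fixture(scope="session")
def params_printed(params) -> ChannelParams:
    return params.with_mode("as_printed")


@pytest.fixture(scope="session")
def gamma_mid(params) -> float:
    return midpoint_tension(params)


@pytest.fixture(scope="session")
def fast_ramp(params, gamma_mid):
    """0.25 s erasure ramp from the model midpoint to 3 kBT/nm^2."""
    return make_erasure_ramp(gamma_mid, 3.0, 0.25)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
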