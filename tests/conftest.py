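import numpy as np
import pytest

from robustqc import (
    DistributionSpec,
    IndicatorSample,
    gamma_params_from_skewness,
    simulate_indicator,
)


@pytest.fixture
def gamma_sample():
    """Factory: a seeded Gamma indicator sample with mean 8."""

    def make(skewness: float, n: int = 1000, seed: int = 42) -> IndicatorSample:
        spec = DistributionSpec.gamma(gamma_params_from_skewness(8.0, skewness))
        return simulate_indicator(spec, n, seed)

    return make


@pytest.fixture
def normal_sample():
    def make(n: int = 1000, seed: int = 42, mean: float = 8.0, sd: float = 1.0):
        return simulate_indicator(DistributionSpec.normal(mean, sd), n, seed)

    return make
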