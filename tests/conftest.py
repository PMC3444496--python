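import numpy as np
import pytest

from hivdes import default_parameters, default_two_arm_parameters


@pytest.fixture(scope="session")
def params_nnrti():
    return default_parameters("NNRTI")


@pytest.fixture(scope="session")
def params_pir():
    return default_parameters("PIr")


@pytest.fixture(scope="session")
def two_arm():
    return default_two_arm_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_930)


class FixedUniformRng:
    """Stub RNG whose uniform draws are a constant; medians come out exactly."""

    def __init__(self, u=0.5):
        self.u = u

    def random(self, size=None):
        if size is None:
            return self.u
        return np.full(size, self.u)

    def standard_normal(self, size=None):
        return 0.0 if size is None else np.zeros(size)

    def triangular(self, lo, mode, hi):
        return mode

    def uniform(self, lo, hi, size=None):
        return lo + (hi - lo) * self.u


@pytest.fixture()
def fixed_rng():
    return FixedUniformRng(0.5)
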