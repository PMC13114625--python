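import numpy as np
import pytest

from mininf import DiscreteJointDistribution, VariableSet


def make_xor(names=("A", "B", "C")) -> DiscreteJointDistribution:
    """A, B independent uniform bits, third variable their XOR."""
    p = np.zeros((2, 2, 2))
    for a in range(2):
        for b in range(2):
            p[a, b, a ^ b] = 0.25
    return DiscreteJointDistribution(VariableSet(names, [2, 2, 2]), p)


def make_copy_pair() -> DiscreteJointDistribution:
    """Two perfectly correlated uniform bits."""
    p = np.array([[0.5, 0.0], [0.0, 0.5]])
    return DiscreteJointDistribution(VariableSet(["A", "B"], [2, 2]), p)


def make_independent_bits(names=("A", "B")) -> DiscreteJointDistribution:
    n = len(names)
    p = np.full((2,) * n, 2.0 ** -n)
    return DiscreteJointDistribution(VariableSet(names, [2] * n), p)


def random_distribution(names, rng, cards=None) -> DiscreteJointDistribution:
    cards = cards or [2] * len(names)
    return DiscreteJointDistribution.random(VariableSet(names, cards), rng)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def xor_dist():
    return make_xor()


@pytest.fixture
def copy_pair():
    return make_copy_pair()
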