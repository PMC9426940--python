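import numpy as np
import pytest

from spinwalk import HADAMARD, InitialSpec, StepOperator, make_point_state


@pytest.fixture
def hadamard_op():
    return StepOperator(HADAMARD)


@pytest.fixture
def symmetric_state():
    """Unbiased point state (1, i)/sqrt(2) ⊗ |0>."""
    return make_point_state(InitialSpec())


def variance(sites: np.ndarray, probs: np.ndarray) -> float:
    probs = probs / probs.sum()
    mu = float(np.sum(sites * probs))
    return float(np.sum((sites - mu) ** 2 * probs))
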