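import numpy as np
import pytest

from dualtf.io_formats import ProfileSet, SequenceSet
from dualtf.site_scanner import PWM, UNIFORM_BACKGROUND


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_pwm():
    """Near-deterministic 4-column PWM with consensus ACGT."""
    probs = np.full((4, 4), 0.02)
    for i, base in enumerate("ACGT"):
        probs[i, "ACGT".index(base)] = 0.94
    return PWM("toy", probs, UNIFORM_BACKGROUND)


@pytest.fixture
def random_pwm_factory(rng):
    def make(length=6, name="rand", background=None):
        probs = rng.dirichlet(np.ones(4), size=length)
        return PWM(name, probs, background if background is not None else UNIFORM_BACKGROUND)

    return make


@pytest.fixture
def dna_set():
    return SequenceSet([("crmA", "ACGTACGTACGT"), ("crmB", "TTTTACGTCCCC")])


@pytest.fixture
def profile_set():
    axis = np.array([10.0, 20.0, 30.0, 40.0])
    return ProfileSet(axis, {"tf1": np.array([1.0, 0.5, 0.25, 0.0]),
                             "tf2": np.array([0.0, 0.5, 1.0, 0.5])})
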