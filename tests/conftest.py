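import numpy as np
import pytest

from liftwalk.line3 import Line3Angles, build_line3
from liftwalk.runner import get_scenario


@pytest.fixture(scope="session")
def line3_41_blocks():
    """Line-graph blocks for the published no-disinfection angle table."""
    return build_line3(Line3Angles(**get_scenario("no_disinfection").angles))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240521)


def random_density(rng, d):
    """Random mixed density operator of dimension d."""
    A = rng.normal(size=(d, d)) + 1j * rng.normal(size=(d, d))
    rho = A @ A.conj().T
    return rho / np.trace(rho)


def random_pure(rng, d):
    v = rng.normal(size=d) + 1j * rng.normal(size=d)
    return v / np.linalg.norm(v)
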