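import numpy as np
import pytest

from dnaclamp.footprint import UnzipTheory
from dnaclamp.kinetics import thiocoraline_model
from dnaclamp.synth import gen_hairpin


@pytest.fixture(scope="session")
def model():
    """Reference three-state model of the bis-intercalator."""
    return thiocoraline_model()


@pytest.fixture(scope="session")
def hairpin480():
    """480-bp footprinting hairpin with an ACGT motif planted at 200."""
    return gen_hairpin(480, planted_motifs=[("ACGT", 200)], seed=3)


@pytest.fixture(scope="session")
def theory480(hairpin480):
    return UnzipTheory.from_construct(hairpin480)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
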