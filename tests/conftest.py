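import numpy as np
import pytest

from hydropack.builder import build_peptide
from hydropack.fixtures import make_bridged_dimer
from hydropack.packer import AnnealSchedule
from hydropack.structure import build_polar_hydrogens


@pytest.fixture(scope="session")
def tripeptide():
    """ALA-SER-ALA with polar hydrogens, ideal geometry."""
    return build_polar_hydrogens(build_peptide(["ALA", "SER", "ALA"]))


@pytest.fixture(scope="session")
def tetrapeptide():
    return build_polar_hydrogens(build_peptide(["ALA", "SER", "ASN", "ALA"]))


@pytest.fixture(scope="session")
def bridged_dimer():
    """Idealized two-peptide system with a planted bridging-water site."""
    return make_bridged_dimer(jitter=0.0, seed=0)


@pytest.fixture()
def fast_schedule():
    """Short annealing schedule for unit tests."""
    return AnnealSchedule(n_cycles=2, steps_per_cycle=400, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
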