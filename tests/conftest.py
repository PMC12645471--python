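import numpy as np
import pytest

from haloscope.ligand import parse_ligand
from haloscope.synthetic import ReceptorSpec, gen_receptor


@pytest.fixture(scope="session")
def phenol():
    return parse_ligand("Oc1ccccc1")


@pytest.fixture(scope="session")
def benzene():
    return parse_ligand("c1ccccc1")


@pytest.fixture(scope="session")
def dihydroxybenzophenone():
    return parse_ligand("Oc1ccc(cc1)C(=O)c1ccc(O)cc1")


@pytest.fixture(scope="session")
def carved_receptor():
    """Single 10x10x10 A cavity with a channel to the surface."""
    structure, truth = gen_receptor(ReceptorSpec(), seed=7)
    return structure, truth


@pytest.fixture()
def refs():
    """K79/D307 reference points 6 A apart (the co-stabilising pair)."""
    return np.zeros(3), np.array([6.0, 0.0, 0.0])
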