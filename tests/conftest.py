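import warnings

import numpy as np
import pytest

from gmmrefine import chemdata, synthetic
from gmmrefine.geometry import GeometryEngine
from gmmrefine.synthetic import FixtureSpec

warnings.filterwarnings("ignore", message=".*Sobol.*")


@pytest.fixture(scope="session")
def templates():
    return chemdata.load_templates()


@pytest.fixture(scope="session")
def helix_model():
    return synthetic.make_toy_structure(FixtureSpec("AAAAAAAALL", recipe="helix"))


@pytest.fixture(scope="session")
def helix_topo(helix_model, templates):
    return chemdata.compile_topology(helix_model, templates)


@pytest.fixture(scope="session")
def helix_engine(helix_topo, templates):
    return GeometryEngine(helix_topo, templates)


@pytest.fixture(scope="session")
def rna_model():
    return synthetic.make_toy_structure(
        FixtureSpec("GGACUG", molecule="rna")
    )


@pytest.fixture(scope="session")
def rna_topo(rna_model, templates):
    return chemdata.compile_topology(rna_model, templates)


@pytest.fixture(scope="session")
def rna_engine(rna_topo, templates):
    return GeometryEngine(rna_topo, templates)


@pytest.fixture(scope="session")
def mixed_model():
    return synthetic.make_toy_structure(
        FixtureSpec("GSNDHKRWEF", recipe="strand")
    )


def rmsd(a, b):
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
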