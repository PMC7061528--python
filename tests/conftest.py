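import numpy as np
import pytest

from grn_landscape.model import (
    GeneNode,
    NetworkSpec,
    ParameterSet,
    Regulation,
    compile_network,
    default_network,
)


@pytest.fixture(scope="session")
def default_net():
    return default_network()


@pytest.fixture(scope="session")
def default_compiled(default_net):
    return compile_network(default_net)


def make_single_gene(g0=50.0, k=1.0) -> NetworkSpec:
    """One unregulated gene: a pure birth-death process."""
    return NetworkSpec(
        [GeneNode("A", "protein", g0, k)], [], ParameterSet(g0=g0, k=k)
    )


def make_self_repressor(m=1, omega=1000.0, g0=50.0) -> NetworkSpec:
    """One gene with a single repressing site bound by its own product."""
    params = ParameterSet(g0=g0, omega=omega)
    return NetworkSpec(
        [GeneNode("A", "protein", g0, 1.0)],
        [Regulation("A", "A", "repression", m=m)],
        params,
    )


def make_two_gene_repressor(m=1, omega=1000.0) -> NetworkSpec:
    """Gene B repressed by monomer/dimer binding of unregulated gene A."""
    params = ParameterSet(omega=omega)
    return NetworkSpec(
        [GeneNode("A", "protein", 20.0, 1.0), GeneNode("B", "protein", 50.0, 1.0)],
        [Regulation("A", "B", "repression", m=m)],
        params,
    )


@pytest.fixture
def single_gene():
    return make_single_gene()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
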