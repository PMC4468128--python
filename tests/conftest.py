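import numpy as np
import pytest

from cimld.lattice import make_simple_lattice, simulate_phenotypes
from cimld.ril_sim import (
    Chromosome,
    GeneticMap,
    build_grid,
    simulate_ril_genotypes,
    uniform_map,
)


@pytest.fixture(scope="session")
def small_map():
    """One 60 cM chromosome with 7 evenly spaced markers."""
    return uniform_map(n_chromosomes=1, length=60.0, markers_per_chromosome=7)


@pytest.fixture(scope="session")
def paper_map():
    """The five-chromosome, 150 cM, 16-marker genome of the study design."""
    return uniform_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_trial():
    """A complete k=3 lattice trial with known genetic values."""
    rng = np.random.default_rng(7)
    layout = make_simple_lattice(3, rng)
    g = rng.normal(0.0, 1.0, 9)
    records = simulate_phenotypes(g, layout, h2=0.6, delta=1.5, rep_effect=2.0, rng=rng)
    return layout, g, records
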