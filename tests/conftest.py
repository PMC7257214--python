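import numpy as np
import pytest

from compbias import simulate as sim
from compbias.genome_io import extract_cds


@pytest.fixture(scope="session")
def small_spec():
    spec = sim.SimulationSpec(seed=11)
    spec.genome.length = 60_000
    spec.cds.n_genes = 40
    return spec


@pytest.fixture(scope="session")
def genome_bundle(small_spec):
    """Genome with embedded genes + models + generation truth."""
    genome = sim.sim_genome(small_spec)
    embedded, models, truth = sim.sim_cds_set(small_spec, genome)
    return embedded, models, truth


@pytest.fixture(scope="session")
def cds_set(genome_bundle):
    embedded, models, _ = genome_bundle
    return [extract_cds(embedded, m) for m in models]


@pytest.fixture(scope="session")
def cross_bundle():
    spec = sim.SimulationSpec(seed=5)
    matrix, truth = sim.sim_cross(spec)
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
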