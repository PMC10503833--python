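import pytest

from pctrace import io as pio
from pctrace import simulate as sim


@pytest.fixture(scope="session")
def germline():
    return sim.default_germline_set()


@pytest.fixture(scope="session")
def base_sim(germline):
    """A noiseless repertoire at the canonical study size (2000 cells, 150 clones)."""
    config = sim.SimConfig(n_cells=2000, n_clones=150, seed=42)
    contigs, truth = sim.simulate_repertoire(config, germline)
    return config, contigs, truth


@pytest.fixture(scope="session")
def paired_base(base_sim):
    _, contigs, _ = base_sim
    return pio.pair_cell_chains(contigs)


@pytest.fixture(scope="session")
def lineage_sim(germline):
    """1000 independent clonal lineages (one cell each) for per-lineage statistics."""
    config = sim.SimConfig(n_cells=1000, n_clones=1000, seed=7)
    contigs, truth = sim.simulate_repertoire(config, germline)
    return config, contigs, truth


@pytest.fixture(scope="session")
def small_sim(germline):
    config = sim.SimConfig(n_cells=300, n_clones=40, seed=11)
    contigs, truth = sim.simulate_repertoire(config, germline)
    return config, contigs, truth


@pytest.fixture(scope="session")
def expression_sim(germline):
    """Equal-proportion 9-state expression dataset, 500 cells per state."""
    props = {s: 1.0 / 9.0 for s in sim.SimConfig().state_proportions}
    config = sim.SimConfig(
        n_cells=4500, n_clones=450, seed=13, state_proportions=props, marker_fold=8.0
    )
    contigs, truth = sim.simulate_repertoire(config, germline)
    adata, marker_map = sim.simulate_expression(truth, config)
    return config, truth, adata, marker_map
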