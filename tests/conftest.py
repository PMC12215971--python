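import numpy as np
import pytest
import scipy.sparse as sp

from growthplate import CountMatrix, SynthConfig, ZoneSpec, simulate_growth_plate

ZONES = ("resting", "proliferative", "pre-hypertrophic", "hypertrophic")


def small_config(n_cells=400, n_genes=600, seed=1, markers=10):
    cfg = SynthConfig(n_cells=n_cells, n_genes=n_genes, seed=seed)
    cfg.zones = [
        ZoneSpec(name, markers, c, 0.1)
        for name, c in zip(ZONES, (0.125, 0.375, 0.625, 0.875))
    ]
    return cfg


@pytest.fixture(scope="session")
def small_synth():
    """400-cell / 600-gene growth plate shared across fast tests."""
    return simulate_growth_plate(small_config())


def make_counts(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(sp.csr_matrix(values), np.array(gene_ids, dtype=object),
                       np.array(cell_ids, dtype=object))


@pytest.fixture
def random_counts():
    rng = np.random.default_rng(7)
    return make_counts(rng.poisson(2.0, size=(30, 100)))
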