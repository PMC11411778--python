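import numpy as np
import pytest

from bigsur import CountMatrix, SimulationSpec, simulate_null


@pytest.fixture
def toy_counts():
    """Two genes x two cells with perfectly anti-correlated counts."""
    return CountMatrix(
        np.array([[2, 0], [0, 2]]),
        gene_ids=np.array(["A", "B"], dtype=object),
        cell_ids=np.array(["c1", "c2"], dtype=object),
    )


@pytest.fixture(scope="session")
def null_1000x999():
    """The standard null benchmark simulation (1000 genes x 999 cells, c=0.5)."""
    spec = SimulationSpec(n_genes=1000, n_cells=999, c=0.5, seed=11)
    counts, truth = simulate_null(spec)
    return counts, truth, spec


@pytest.fixture(scope="session")
def null_small():
    """A small null simulation for pair-level tests (200 genes x 500 cells)."""
    spec = SimulationSpec(n_genes=200, n_cells=500, c=0.5, seed=7)
    counts, truth = simulate_null(spec)
    return counts, truth, spec
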