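import numpy as np
import pytest

from ctascore import ClusterAssignment, ExpressionMatrix, MarkerCatalog


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """4 genes x 6 cells; ta/tb are markers, bg1/bg2 background.

    Cells c1-c3 form cluster "0" (ta high), c4-c6 cluster "1" (tb high).
    """
    genes = ["ta", "tb", "bg1", "bg2"]
    values = np.array(
        [
            [9.0, 8.0, 10.0, 0.0, 0.0, 1.0],  # ta
            [0.0, 1.0, 0.0, 7.0, 9.0, 8.0],   # tb
            [1.0, 2.0, 1.0, 2.0, 1.0, 2.0],   # bg1
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # bg2
        ]
    )
    cells = [f"c{i}" for i in range(1, 7)]
    return ExpressionMatrix(genes, cells, values)


@pytest.fixture
def toy_clusters() -> ClusterAssignment:
    return ClusterAssignment(
        {"c1": "0", "c2": "0", "c3": "0", "c4": "1", "c5": "1", "c6": "1"}
    )


@pytest.fixture
def toy_catalog() -> MarkerCatalog:
    return MarkerCatalog({"A": ["ta"], "B": ["tb"]})


def random_instance(rng: np.random.Generator):
    """Small random scoring instance for oracle cross-checks.

    N <= 5 markers, K <= 4 clusters, <= 30 cells; returns the package
    containers plus the plain-list views the loop oracle consumes.
    """
    n = int(rng.integers(1, 6))
    k = int(rng.integers(1, 5))
    n_extra = int(rng.integers(0, 3))
    n_cells = int(rng.integers(k, 31))
    cluster_of_cell = [int(x) for x in rng.integers(0, k, size=n_cells)]
    cluster_of_cell[:k] = range(k)  # reserve one cell per cluster: none empty
    values = np.round(rng.gamma(1.0, 2.0, size=(n + n_extra, n_cells)) *
                      rng.integers(0, 2, size=(n + n_extra, n_cells)), 3)
    genes = [f"g{i}" for i in range(n + n_extra)]
    cells = [f"c{j}" for j in range(n_cells)]
    expr = ExpressionMatrix(genes, cells, values)
    clusters = ClusterAssignment(
        {cells[j]: str(cluster_of_cell[j]) for j in range(n_cells)},
        [str(c) for c in range(k)],
    )
    return expr, clusters, genes[:n], values.tolist(), cluster_of_cell, list(range(n))
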