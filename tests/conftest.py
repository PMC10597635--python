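"""Shared fixtures: synthetic datasets, pipeline runs and small named graphs.

The expensive simulated-annealing pipeline runs are session-scoped so every
test file scores the same run instead of recomputing it.
"""

import numpy as np
import pytest

import annealclust as ac


# -- small named graphs --------------------------------------------------------


def single_edge() -> ac.SNNGraph:
    return ac.SNNGraph(2, {(0, 1): 1.0})


def two_triangles() -> ac.SNNGraph:
    return ac.SNNGraph(
        6, {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0, (3, 4): 1.0, (3, 5): 1.0, (4, 5): 1.0}
    )


def barbell() -> ac.SNNGraph:
    """Two 5-cliques joined by one bridge edge."""
    w = {}
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                w[(base + i, base + j)] = 1.0
    w[(4, 5)] = 1.0
    return ac.SNNGraph(10, w)


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> ac.SNNGraph:
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                weights[(i, j)] = float(rng.uniform(0.05, 1.0))
    if not weights:
        weights[(0, 1)] = 0.5
    return ac.SNNGraph(n, weights)


# -- synthetic data ------------------------------------------------------------


@pytest.fixture(scope="session")
def two_cluster_data():
    spec = ac.SyntheticSpec(n_cells=100, n_genes=500, k_clusters=2, overlap=0.0, seed=1)
    return ac.generate(spec)


@pytest.fixture(scope="session")
def three_cluster_data():
    spec = ac.SyntheticSpec(n_cells=200, n_genes=1000, k_clusters=3, overlap=0.0, seed=7)
    return ac.generate(spec)


@pytest.fixture(scope="session")
def preset_data():
    return ac.generate(ac.closely_related_preset(n_cells=250, seed=1))


# -- session pipeline runs -----------------------------------------------------


@pytest.fixture(scope="session")
def three_cluster_run(three_cluster_data):
    matrix, _ = three_cluster_data
    return ac.cluster_expression(matrix, seed=7)


@pytest.fixture(scope="session")
def preset_run(preset_data):
    matrix, _ = preset_data
    return ac.cluster_expression(matrix, seed=1)


@pytest.fixture(scope="session")
def preset_ensemble(preset_run):
    return ac.build_ensemble(
        preset_run.clustering, preset_run.graph, preset_run.config, top_n=8
    )
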