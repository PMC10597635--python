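"""End-to-end convenience: counts -> embedding -> SNN graph -> clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_io import ExpressionMatrix, normalize_and_reduce
from .recursive_clustering import ClusterConfig, ClusteringResult, recursive_cluster
from .samplers import Sampler, SimulatedAnnealingSampler
from .snn_graph import DEFAULT_PRUNE, SNNGraph, build_snn_graph

__all__ = ["PipelineResult", "cluster_expression"]


@dataclass
class PipelineResult:
    embedding: np.ndarray
    graph: SNNGraph
    clustering: ClusteringResult
    config: ClusterConfig


def cluster_expression(
    matrix: ExpressionMatrix,
    n_components: int = 20,
    k_neighbors: int = 20,
    prune: float = DEFAULT_PRUNE,
    sampler: Sampler | None = None,
    gamma: float | None = None,
    reads: int = 500,
    min_size: int = 10,
    max_depth: int = 10,
    confidence_threshold: float = 0.05,
    seed: int = 0,
) -> PipelineResult:
    """Normalize, embed, build the SNN graph and recursively bipartition.

    ``gamma=None`` re-derives the balance multiplier per recursion node from
    the subgraph's edge weight; the default sampler is simulated annealing.
    """
    if sampler is None:
        sampler = SimulatedAnnealingSampler()
    embedding = normalize_and_reduce(matrix, n_components=n_components, seed=seed)
    graph = build_snn_graph(embedding, k=k_neighbors, prune=prune)
    config = ClusterConfig(
        gamma=gamma,
        reads=reads,
        min_size=min_size,
        max_depth=max_depth,
        confidence_threshold=confidence_threshold,
        sampler=sampler,
        seed=seed,
    )
    clustering = recursive_cluster(graph, config)
    return PipelineResult(embedding=embedding, graph=graph, clustering=clustering, config=config)
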