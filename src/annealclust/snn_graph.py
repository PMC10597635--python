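"""Shared-nearest-neighbor (SNN) graphs over cells.

Cells are nodes; each cell is linked to others with which it shares nearest
neighbors, and the edge weight is the Jaccard similarity of the two
k-nearest-neighbor sets (each set including the cell itself).  Weakly
overlapping neighborhoods are pruned below a threshold.  This is the Seurat
style construction; an alternative mode computes Jaccard similarity between
binarized expression profiles instead of neighbor sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import GraphError

__all__ = ["SNNGraph", "jaccard_index", "build_snn_graph"]

DEFAULT_PRUNE = 1.0 / 15.0


@dataclass
class SNNGraph:
    """Undirected weighted graph on ``n_nodes`` cells.

    ``weights`` maps each unordered edge ``(i, j)`` with ``i < j`` to its
    Jaccard weight in ``(0, 1]``.  Nodes left with no edges after pruning stay
    in the graph (and become singleton clusters downstream).
    """

    n_nodes: int
    weights: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise GraphError("graph needs at least one node")
        for (i, j), w in self.weights.items():
            if i == j:
                raise GraphError(f"self-loop on node {i}")
            if not (0 <= i < j < self.n_nodes):
                raise GraphError(f"edge ({i}, {j}) is not an ordered in-range pair")
            if not (0.0 < w <= 1.0):
                raise GraphError(f"edge ({i}, {j}) weight {w} outside (0, 1]")

    # -- basic queries ------------------------------------------------------

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.weights)

    def weight(self, i: int, j: int) -> float:
        return self.weights.get((min(i, j), max(i, j)), 0.0)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.weights:
            deg[i] += 1
            deg[j] += 1
        return deg

    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(self.n_nodes)}
        for (i, j), w in sorted(self.weights.items()):
            adj[i].append((j, w))
            adj[j].append((i, w))
        return adj

    # -- structure ----------------------------------------------------------

    def subgraph(self, nodes) -> tuple["SNNGraph", np.ndarray]:
        """Induced subgraph on ``nodes``; returns (graph, original-ids array).

        Local node ``k`` of the subgraph corresponds to ``ids[k]`` in ``self``;
        ``ids`` is sorted ascending.
        """
        ids = np.asarray(sorted(set(int(v) for v in nodes)), dtype=np.int64)
        if ids.size == 0:
            raise GraphError("empty node subset")
        if ids[0] < 0 or ids[-1] >= self.n_nodes:
            raise GraphError("subset node id out of range")
        local = {int(v): k for k, v in enumerate(ids)}
        sub = {}
        for (i, j), w in self.weights.items():
            if i in local and j in local:
                a, b = local[i], local[j]
                sub[(min(a, b), max(a, b))] = w
        return SNNGraph(n_nodes=ids.size, weights=sub), ids

    def connected_components(self) -> list[list[int]]:
        """Components as sorted node lists, ordered by smallest member."""
        mat = self.to_sparse()
        n_comp, labels = connected_components(mat, directed=False)
        comps: list[list[int]] = [[] for _ in range(n_comp)]
        for node, c in enumerate(labels):
            comps[c].append(node)
        return sorted(comps, key=lambda c: c[0])

    def to_sparse(self) -> sp.csr_matrix:
        if not self.weights:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        rows, cols, vals = [], [], []
        for (i, j), w in self.weights.items():
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n_nodes, self.n_nodes))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from((i, j, w) for (i, j), w in self.weights.items())
        return g

    # -- persistence --------------------------------------------------------

    def save_edgelist(self, path) -> None:
        """Write ``i<TAB>j<TAB>weight`` lines (0-based, one edge per line)."""
        with open(path, "w") as fh:
            fh.write(f"# n_nodes={self.n_nodes}\n")
            for (i, j), w in sorted(self.weights.items()):
                fh.write(f"{i}\t{j}\t{w:.10g}\n")

    @classmethod
    def load_edgelist(cls, path) -> "SNNGraph":
        path = Path(path)
        weights: dict[tuple[int, int], float] = {}
        n_nodes = 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "n_nodes=" in line:
                        n_nodes = int(line.split("n_nodes=")[1])
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise GraphError(f"{path}: malformed edge line {line!r}")
                i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
                weights[(min(i, j), max(i, j))] = w
                n_nodes = max(n_nodes, i + 1, j + 1)
        return cls(n_nodes=n_nodes, weights=weights)


def jaccard_index(a, b) -> float:
    """``|a ∩ b| / |a ∪ b|`` for finite sets; undefined (error) when both empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise GraphError("Jaccard index of two empty sets is undefined")
    return len(a & b) / len(union)


def _knn_indices(embedding: np.ndarray, k: int) -> np.ndarray:
    """Deterministic k-nearest-neighbor indices (self excluded).

    Distance ties are broken by lower node index so duplicated points never
    make the graph depend on floating-point ordering quirks.
    """
    n = embedding.shape[0]
    dist = squareform(pdist(embedding))
    np.fill_diagonal(dist, np.inf)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))
        out[i] = order[:k]
    return out


def build_snn_graph(
    embedding: np.ndarray,
    k: int = 20,
    prune: float = DEFAULT_PRUNE,
    mode: str = "snn",
    counts=None,
) -> SNNGraph:
    """Build the SNN graph of an ``(n_cells, d)`` embedding.

    An edge ``(i, j)`` is kept iff the Jaccard similarity of the two
    neighborhoods (k nearest Euclidean neighbors plus the cell itself) exceeds
    ``prune``; that similarity is the edge weight.

    With ``mode="binary-expression"`` the weight is instead the Jaccard
    similarity of the sets of expressed (nonzero-count) genes of the two
    cells, computed over the pairs of cells that are nearest neighbors;
    ``counts`` (cells x genes, sparse or dense) must then be given.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    n = embedding.shape[0]
    if not np.isfinite(embedding).all():
        raise GraphError("embedding contains non-finite values")
    if k <= 0:
        raise GraphError("k must be positive")
    if k >= n:
        raise GraphError(f"k={k} must be smaller than the number of cells ({n})")
    if not (0.0 <= prune < 1.0):
        raise GraphError("prune threshold must lie in [0, 1); 1.0 would delete every edge")
    if mode not in ("snn", "binary-expression"):
        raise GraphError(f"unknown jaccard mode {mode!r}")

    knn = _knn_indices(embedding, k)

    if mode == "binary-expression":
        if counts is None:
            raise GraphError("binary-expression mode requires the counts matrix")
        x = sp.csr_matrix(counts)
        if x.shape[0] != n:
            raise GraphError("counts row count does not match the embedding")
        x.data = np.ones_like(x.data)
        nnz = np.asarray(x.sum(axis=1)).ravel()
        weights: dict[tuple[int, int], float] = {}
        inter_mat = (x @ x.T).tocoo()
        candidate = set()
        for i in range(n):
            for j in knn[i]:
                candidate.add((min(i, int(j)), max(i, int(j))))
        inter_lookup = {}
        for i, j, v in zip(inter_mat.row, inter_mat.col, inter_mat.data):
            if i < j:
                inter_lookup[(int(i), int(j))] = v
        for i, j in candidate:
            inter = inter_lookup.get((i, j), 0.0)
            union = nnz[i] + nnz[j] - inter
            if union <= 0:
                continue
            w = inter / union
            if w > prune:
                weights[(i, j)] = float(w)
        return SNNGraph(n_nodes=n, weights=weights)

    # neighbor-set mode: sparse indicator of {i} ∪ kNN(i), all-pairs overlap
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([knn, np.arange(n)[:, None]], axis=1).ravel()
    ind = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    inter = (ind @ ind.T).tocoo()
    weights = {}
    set_size = k + 1
    for i, j, v in zip(inter.row, inter.col, inter.data):
        if i >= j:
            continue
        w = v / (2 * set_size - v)
        if w > prune:
            weights[(int(i), int(j))] = float(w)
    return SNNGraph(n_nodes=n, weights=weights)
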