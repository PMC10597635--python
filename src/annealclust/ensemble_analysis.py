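"""Analysis of the low-energy solution ensemble as alternative clusterings.

Annealing-style samplers return many low-energy states, not one answer.  Each
frequently sampled state of a recursion node is an alternative cut; swapping it
in (one node at a time, the rest of the tree re-derived deterministically)
yields an ensemble of full partitionings that can be deduplicated, ranked by
energy, scored (silhouette, Rand index) and compared against a multi-restart
k-means baseline — the single-algorithm view the ensemble is meant to improve
on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, rand_score, silhouette_samples

from .errors import ClusteringError
from .recursive_clustering import (
    ClusterConfig,
    ClusteringResult,
    PartitionNode,
    canonicalize_state,
    recursive_cluster,
)
from .snn_graph import SNNGraph

__all__ = [
    "SolutionEnsemble",
    "canonicalize",
    "build_ensemble",
    "rand_index",
    "adjusted_rand_index",
    "silhouette",
    "kmeans_baseline",
]


def canonicalize(x) -> np.ndarray:
    """Representative of the complement pair {x, 1-x}: the lexicographically
    smaller of the two (both encode the same bipartition)."""
    return canonicalize_state(np.asarray(x, dtype=np.uint8))


def _canonical_labels(labels: np.ndarray) -> tuple[int, ...]:
    """Partition signature invariant to cluster renumbering: relabel clusters
    by order of first appearance."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


@dataclass
class SolutionEnsemble:
    """Distinct full partitionings with energies, frequencies and scores."""

    partitions: list[np.ndarray]
    energies: list[float]
    frequencies: list[int]
    scores: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.partitions)

    def score(self, embedding=None, reference=None) -> None:
        """Attach silhouette and (adjusted) Rand index records per partition."""
        self.scores = []
        for labels in self.partitions:
            rec: dict = {"n_clusters": len(set(labels.tolist()))}
            if embedding is not None:
                try:
                    rec["silhouette"] = silhouette(embedding, labels)
                except ClusteringError:
                    rec["silhouette"] = float("nan")
            if reference is not None:
                rec["rand_index"] = rand_index(reference, labels)
                rec["adjusted_rand_index"] = adjusted_rand_index(reference, labels)
            self.scores.append(rec)

    def report_json(self) -> str:
        rows = []
        for rank, (labels, e, f) in enumerate(
            zip(self.partitions, self.energies, self.frequencies)
        ):
            row = {
                "rank": rank,
                "energy": float(e),
                "frequency": int(f),
                "n_clusters": len(set(labels.tolist())),
            }
            if self.scores:
                row.update({k: v for k, v in self.scores[rank].items() if k != "n_clusters"})
            rows.append(row)
        return json.dumps(rows, indent=1)


def build_ensemble(
    result: ClusteringResult,
    g: SNNGraph,
    config: ClusterConfig,
    top_n: int = 10,
) -> SolutionEnsemble:
    """Alternative full clusterings from the per-node solution spectra.

    For every tree node that was sampled, each of its most sampled distinct
    admissible states is substituted in turn (all other nodes kept at their
    chosen states; the subtree below the substitution is re-clustered
    deterministically with the same configuration).  At an internal node the
    substitution replaces the chosen cut; at a leaf that stopped on low
    confidence it splits the leaf — these are the "alternative subpopulation"
    solutions.  Each substitution yields one candidate partition whose
    reported energy is the substituted state's energy under that node's BQM
    and whose frequency is its occurrence count.  Candidates are deduplicated
    up to cluster renumbering and ranked by energy.
    """
    if top_n < 1:
        raise ClusteringError("top_n must be >= 1")

    candidates: list[tuple[np.ndarray, float, int]] = []

    def visit(node: PartitionNode) -> None:
        if node.sampleset is not None:
            ss = node.sampleset
            ids = np.asarray(node.node_ids, dtype=np.int64)
            seen: set[tuple[int, ...]] = set()
            for row, e, occ in zip(ss.states, ss.energies, ss.occurrences):
                x = canonicalize(row)
                key = tuple(int(b) for b in x)
                if key in seen:
                    continue
                seen.add(key)
                ones = int(x.sum())
                if min(ones, x.size - ones) < config.min_size:
                    continue
                labels = _substituted_labels(result, g, config, node, ids, x)
                candidates.append((labels, float(e), int(occ)))
                if len(seen) >= top_n:
                    break
        if node.children is not None:
            visit(node.children[0])
            visit(node.children[1])

    visit(result.tree)
    if not candidates:
        # degenerate tree (single leaf): the clustering itself is the ensemble
        candidates = [(result.labels.copy(), 0.0, 1)]

    dedup: dict[tuple[int, ...], tuple[np.ndarray, float, int]] = {}
    for labels, e, occ in candidates:
        key = _canonical_labels(labels)
        if key in dedup:
            old_labels, old_e, old_occ = dedup[key]
            dedup[key] = (old_labels, min(old_e, e), old_occ + occ)
        else:
            dedup[key] = (labels, e, occ)
    rows = sorted(dedup.values(), key=lambda t: (t[1], _canonical_labels(t[0])))[:top_n]
    return SolutionEnsemble(
        partitions=[r[0] for r in rows],
        energies=[r[1] for r in rows],
        frequencies=[r[2] for r in rows],
    )


def _substituted_labels(
    result: ClusteringResult,
    g: SNNGraph,
    config: ClusterConfig,
    target: PartitionNode,
    ids: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    """Full labeling with ``target``'s split replaced by state ``x`` and the
    re-split subsets re-clustered; all other leaves keep their membership."""
    side_a = ids[np.flatnonzero(x == 0)]
    side_b = ids[np.flatnonzero(x == 1)]
    new_parts: list[np.ndarray] = []
    for side in (side_a, side_b):
        sg, sids = g.subgraph(side)
        sub_res = recursive_cluster(sg, config)
        for k in range(sub_res.n_clusters):
            new_parts.append(sids[np.flatnonzero(sub_res.labels == k)])

    labels = np.full(g.n_nodes, -1, dtype=np.int64)
    next_label = 0
    target_cells = set(int(i) for i in ids)
    for leaf in result.tree.leaves():
        cells = [i for i in leaf.node_ids if i not in target_cells]
        if cells:
            labels[np.asarray(cells, dtype=np.int64)] = next_label
            next_label += 1
    for part in new_parts:
        labels[part] = next_label
        next_label += 1
    return labels


def rand_index(labels_a, labels_b) -> float:
    """Raw Rand index: fraction of point pairs the two partitions agree on."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ClusteringError(f"label length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ClusteringError("need at least two points")
    return float(rand_score(a, b))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index (0 expected for random labelings)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ClusteringError(f"label length mismatch: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def silhouette(embedding, labels) -> float:
    """Mean silhouette ``(b - a) / max(a, b)``; singleton clusters score 0."""
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ClusteringError("silhouette is undefined for a single cluster")
    if uniq.size == labels.size:
        return 0.0  # every cluster a singleton: all scores are 0 by convention
    return float(np.mean(silhouette_samples(embedding, labels)))


def kmeans_baseline(
    embedding,
    k: int,
    restarts: int = 100,
    seed: int = 0,
    reference=None,
) -> pd.DataFrame:
    """Score distribution of ``restarts`` independent Lloyd's-algorithm runs.

    One random initialization per restart, so the rows trace the local-minimum
    landscape k-means actually explores; columns: inertia, silhouette, and
    (with ``reference``) rand_index / adjusted_rand_index.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    n = embedding.shape[0]
    if restarts < 1:
        raise ClusteringError("restarts must be >= 1")
    if k > n:
        raise ClusteringError(f"k={k} exceeds the number of points ({n})")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=1, random_state=rs).fit(embedding)
        rec: dict = {"inertia": float(km.inertia_)}
        try:
            rec["silhouette"] = silhouette(embedding, km.labels_)
        except ClusteringError:
            rec["silhouette"] = float("nan")
        if reference is not None:
            rec["rand_index"] = rand_index(reference, km.labels_)
            rec["adjusted_rand_index"] = adjusted_rand_index(reference, km.labels_)
        rows.append(rec)
    return pd.DataFrame(rows)
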