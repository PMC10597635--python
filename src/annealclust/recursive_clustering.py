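"""Recursive bipartitioning of the SNN graph by balanced min-cut sampling.

Each recursion node builds the balanced min-cut BQM of its induced subgraph,
samples low-energy states, and splits on the best admissible state (both sides
at least ``min_size`` cells, after canonicalizing away the 0/1 complement
symmetry).  Recursion stops on small subsets, at a depth guard, or when the
sampled solution ensemble shows no consensus — measured by the energy variance
of the most frequently sampled states, normalized to be scale-free.

Disconnected subgraphs are split along connected components before any
sampling, so zero-cut components are never merged into one cluster.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ClusteringError
from .qubo_models import (
    BinaryQuadraticModel,
    cut_weight,
    default_mincut_gamma,
    mincut_family,
)
from .samplers import ExactSampler, Sampler, SampleSet
from .snn_graph import SNNGraph

__all__ = [
    "ClusterConfig",
    "PartitionNode",
    "ClusteringResult",
    "bipartition",
    "stopping_confidence",
    "recursive_cluster",
    "tune_gamma",
]


@dataclass
class ClusterConfig:
    """Knobs of the recursive clustering procedure.

    gamma: balance multiplier; None means the per-subgraph default
        ``2 W / |V|^2`` is re-derived at every recursion node.
    reads: sample reads per node (ignored by the exact sampler).
    min_size: minimal admissible cluster size, in cells.
    confidence_threshold: stop when the normalized energy variance of the
        ``top_m`` most frequent states exceeds this (no consensus cut).
    cut_threshold: stop when the chosen split severs more than this fraction
        of the subgraph's total edge weight — a homogeneous cell population
        has no cheap balanced cut, so an expensive one is not a real cluster
        boundary.
    """

    gamma: float | None = None
    reads: int = 500
    min_size: int = 10
    max_depth: int = 10
    confidence_threshold: float = 0.05
    cut_threshold: float = 0.1
    top_m: int = 5
    sampler: Sampler = field(default_factory=ExactSampler)
    seed: int = 0


@dataclass
class PartitionNode:
    """One node of the recursive bipartition tree."""

    node_ids: list[int]
    children: tuple["PartitionNode", "PartitionNode"] | None = None
    sampleset: SampleSet | None = None
    gamma_used: float | None = None
    stop_reason: str = "none"  # none | min_size | low_confidence | max_depth

    def leaves(self) -> list["PartitionNode"]:
        if self.children is None:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()

    def to_dict(self) -> dict:
        d: dict = {
            "n_cells": len(self.node_ids),
            "stop_reason": self.stop_reason,
            "gamma_used": self.gamma_used,
        }
        if self.sampleset is not None:
            d["top_energies"] = [float(e) for e in self.sampleset.energies[:5]]
        if self.children is not None:
            d["children"] = [c.to_dict() for c in self.children]
        else:
            d["node_ids"] = [int(i) for i in self.node_ids]
        return d


@dataclass
class ClusteringResult:
    """Per-cell labels plus the bipartition tree that produced them."""

    labels: np.ndarray
    tree: PartitionNode

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def tree_json(self) -> str:
        return json.dumps(self.tree.to_dict(), indent=1)

    def save_labels(self, path, cell_ids=None) -> None:
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels):
                name = cell_ids[i] if cell_ids is not None else str(i)
                fh.write(f"{name}\t{int(lab)}\n")


def _node_seed(base_seed: int, sub) -> int:
    """Deterministic per-subset seed so identical subtrees resample identically."""
    payload = np.asarray(sorted(sub), dtype=np.int64).tobytes()
    return (int(base_seed) * 131 + zlib.crc32(payload)) % (2**31 - 1)


def canonicalize_state(x: np.ndarray) -> np.ndarray:
    """Lexicographically smaller of a state and its complement (the two encode
    the same bipartition)."""
    x = np.asarray(x, dtype=np.uint8)
    comp = (1 - x).astype(np.uint8)
    return x if tuple(x) <= tuple(comp) else comp


def _component_split(g: SNNGraph) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic two-way grouping of connected components (zero cut):
    components ordered by decreasing size (ties by smallest member) are
    greedily assigned to the currently lighter side."""
    comps = g.connected_components()
    comps = sorted(comps, key=lambda c: (-len(c), c[0]))
    sides: tuple[list[int], list[int]] = ([], [])
    for comp in comps:
        target = 0 if len(sides[0]) <= len(sides[1]) else 1
        sides[target].extend(comp)
    return np.asarray(sorted(sides[0])), np.asarray(sorted(sides[1]))


def _admissible_split(
    ss: SampleSet, min_size: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """First sampled state (energy order) whose two sides both have >= min_size
    members, as (side0, side1) local index arrays; None when no state qualifies."""
    seen = set()
    for row in ss.states:
        x = canonicalize_state(row)
        key = tuple(x)
        if key in seen:
            continue
        seen.add(key)
        ones = int(x.sum())
        zeros = x.size - ones
        if min(ones, zeros) >= min_size:
            return np.flatnonzero(x == 0), np.flatnonzero(x == 1)
    return None


def bipartition(
    g: SNNGraph,
    sub,
    gamma: float,
    sampler: Sampler,
    reads: int = 500,
    min_size: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None, SampleSet | None]:
    """Split ``sub`` by sampling the induced subgraph's balanced min-cut BQM.

    Returns ``(side_a, side_b, sampleset)`` in original node ids.  When no
    sampled state is admissible (both sides >= ``min_size``) the subset is
    returned undivided as ``(sub, None, sampleset)``.  An edgeless induced
    subgraph is split trivially along its (singleton) components.
    """
    sub = np.asarray(sorted(set(int(v) for v in sub)), dtype=np.int64)
    if sub.size < 2 * min_size:
        raise ClusteringError(
            f"subset of {sub.size} cells cannot produce two clusters of >= {min_size}"
        )
    sg, ids = g.subgraph(sub)
    if not sg.weights:
        a, b = _component_split(sg)
        return ids[a], ids[b], None
    from .qubo_models import MinCutParams, build_mincut_bqm

    bqm = build_mincut_bqm(sg, MinCutParams(gamma=gamma))
    ss = sampler.sample(bqm, num_reads=reads, seed=seed)
    split = _admissible_split(ss, min_size)
    if split is None:
        return ids, None, ss
    return ids[split[0]], ids[split[1]], ss


def stopping_confidence(ss: SampleSet, top_m: int = 5, total_weight: float = 1.0) -> float:
    """Scale-free disagreement among the most frequently sampled solutions.

    Population variance of the energies of the ``top_m`` most frequent distinct
    states, divided by the squared total edge weight of the subgraph's BQM so
    graphs of different size are comparable.  Zero means full consensus.
    """
    if len(ss) == 0:
        raise ClusteringError("empty sample set")
    if top_m < 2:
        raise ClusteringError("top_m must be >= 2")
    top = ss.by_frequency(top_m)
    var = float(np.var(top.energies))
    denom = max(float(total_weight), 1e-12) ** 2
    return var / denom


def recursive_cluster(g: SNNGraph, config: ClusterConfig) -> ClusteringResult:
    """Depth-first recursive bipartitioning of the whole graph.

    A node is split unless it is too small (< 2 * min_size), the depth guard is
    hit, or the split is not confident: either the sampled states disagree too
    much (normalized energy variance of the most frequent states above
    ``confidence_threshold``) or the best admissible cut is too expensive
    relative to the subgraph's edge weight (above ``cut_threshold``), meaning
    the subgraph is a homogeneous population without a real cluster boundary.
    Leaves are numbered left to right to give the final labels.
    """
    if g.n_nodes < 1:
        raise ClusteringError("empty graph")

    def recurse(sub: np.ndarray, depth: int) -> PartitionNode:
        node = PartitionNode(node_ids=[int(i) for i in sub])
        if sub.size < 2 * config.min_size:
            node.stop_reason = "min_size"
            return node
        if depth >= config.max_depth:
            node.stop_reason = "max_depth"
            return node
        sg, ids = g.subgraph(sub)
        comps = sg.connected_components()
        if len(comps) > 1:
            # zero-cut split first: components must never be merged
            a, b = _component_split(sg)
            node.children = (recurse(ids[a], depth + 1), recurse(ids[b], depth + 1))
            return node
        gamma = config.gamma if config.gamma is not None else default_mincut_gamma(sg)
        node.gamma_used = gamma
        seed = _node_seed(config.seed, sub)
        side_a, side_b, ss = bipartition(
            g, sub, gamma, config.sampler, reads=config.reads,
            min_size=config.min_size, seed=seed,
        )
        node.sampleset = ss
        if ss is not None:
            conf = stopping_confidence(ss, config.top_m, total_weight=sg.total_weight())
            if conf > config.confidence_threshold:
                node.stop_reason = "low_confidence"
                return node
        if side_b is None:
            node.stop_reason = "low_confidence"
            return node
        # an expensive cut means no real boundary: cut/W of the chosen split
        total = sg.total_weight()
        if total > 0:
            side_b_set = set(int(i) for i in side_b)
            x = np.asarray([1 if int(i) in side_b_set else 0 for i in ids], dtype=np.uint8)
            if cut_weight(sg, x) / total > config.cut_threshold:
                node.stop_reason = "low_confidence"
                return node
        node.children = (recurse(side_a, depth + 1), recurse(side_b, depth + 1))
        return node

    root = recurse(np.arange(g.n_nodes, dtype=np.int64), 0)
    labels = np.full(g.n_nodes, -1, dtype=np.int64)
    for k, leaf in enumerate(root.leaves()):
        labels[np.asarray(leaf.node_ids, dtype=np.int64)] = k
    if (labels < 0).any():
        raise ClusteringError("internal error: unlabeled cells")  # pragma: no cover
    return ClusteringResult(labels=labels, tree=root)


def tune_gamma(
    g: SNNGraph,
    gammas,
    sampler: Sampler,
    reads: int = 500,
    min_size: int = 1,
    seed: int = 0,
) -> float:
    """Pick the balance multiplier whose best sampled state gives the cleanest
    admissible first cut.

    All candidates share one BQM structure (only the gamma-dependent
    coefficients change, mirroring re-tuning on a fixed annealer embedding).  A
    candidate is admissible only if the *best* canonicalized state it samples
    is a real split with both sides >= ``min_size``; its score is the relative
    cut weight plus the relative size imbalance, and the smallest-scoring
    (ties: smallest) gamma wins.
    """
    gammas = sorted(set(float(gv) for gv in gammas))
    if not gammas:
        raise ClusteringError("no gamma candidates given")
    if min(gammas) < 0:
        raise ClusteringError("gamma candidates must be non-negative")
    family = mincut_family(g)
    total = g.total_weight()
    if total <= 0:
        raise ClusteringError("cannot tune gamma on an edgeless graph")
    best: tuple[float, float] | None = None  # (score, gamma)
    for gamma in gammas:
        bqm = family(gamma)
        ss = sampler.sample(bqm, num_reads=reads, seed=_node_seed(seed, [int(gamma * 1e6)]))
        x = canonicalize_state(ss.states[0])
        ones = int(x.sum())
        zeros = x.size - ones
        if min(ones, zeros) < min_size:
            continue  # degenerate (e.g. all-one-side) ground state: reject
        score = cut_weight(g, x) / total + abs(ones - zeros) / x.size
        if best is None or score < best[0] - 1e-12:
            best = (score, gamma)
    if best is None:
        raise ClusteringError(
            "no gamma candidate produced an admissible split; raise gamma or lower min_size"
        )
    return best[1]
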