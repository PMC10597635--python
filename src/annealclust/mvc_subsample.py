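"""Graph size reduction via minimum-vertex-cover sampling.

A vertex cover touches every edge, so clustering only the covered cells keeps
(at least one endpoint of) every similarity relation while discarding a large
fraction of the nodes of a sparse SNN graph.  The cover is found by sampling
the MVC binary quadratic model; the ``gamma`` multiplier trades cover
completeness against cover size, so sweeping it adjusts how many cells are
kept.  Cells outside the cover inherit labels from their covered neighbors
afterwards.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .errors import ClusteringError
from .qubo_models import MvcParams, build_mvc_bqm, mvc_family
from .samplers import Sampler, SampleSet

__all__ = ["mvc_subsample", "subset_size_sweep", "propagate_labels", "uncovered_edges"]


def _best_cover_state(ss: SampleSet) -> np.ndarray:
    """Among minimum-energy states, prefer the smallest cover, then the
    lexicographically smallest state — determinism under degeneracy."""
    e0 = ss.energies[0]
    tied = [tuple(s) for s, e in zip(ss.states, ss.energies) if e <= e0 + 1e-12]
    tied.sort(key=lambda s: (sum(s), s))
    return np.asarray(tied[0], dtype=np.uint8)


def mvc_subsample(
    g, gamma: float = 2.0, sampler: Sampler = None, reads: int = 500, seed: int = 0
) -> np.ndarray:
    """Node ids selected by the best sampled vertex-cover state.

    For ``gamma > 1`` an exactly sampled ground state is a true cover (leaving
    an edge uncovered always costs more than selecting an endpoint).
    """
    from .samplers import ExactSampler

    if sampler is None:
        sampler = ExactSampler()
    bqm = build_mvc_bqm(g, MvcParams(gamma=gamma))
    ss = sampler.sample(bqm, num_reads=reads, seed=seed)
    x = _best_cover_state(ss)
    return np.flatnonzero(x == 1)


def uncovered_edges(g, selected) -> int:
    """Number of edges with neither endpoint in ``selected``."""
    sel = set(int(i) for i in selected)
    return sum(1 for (i, j) in g.weights if i not in sel and j not in sel)


def subset_size_sweep(
    g, gammas, sampler: Sampler = None, reads: int = 500, seed: int = 0
) -> dict[float, int]:
    """Cover size of the best sampled state per gamma candidate.

    One BQM structure is shared across candidates; only the gamma-scaled
    coefficients are refreshed, mirroring re-tuning on a fixed embedding.
    """
    from .samplers import ExactSampler

    if sampler is None:
        sampler = ExactSampler()
    gammas = [float(gv) for gv in gammas]
    if not gammas or min(gammas) <= 0:
        raise ClusteringError("gamma candidates must be positive")
    family = mvc_family(g)
    sizes: dict[float, int] = {}
    for gamma in gammas:
        ss = sampler.sample(family(gamma), num_reads=reads, seed=seed)
        sizes[gamma] = int(_best_cover_state(ss).sum())
    return sizes


def propagate_labels(g, core_labels: dict[int, int], excluded) -> dict[int, int]:
    """Extend cluster labels from covered (core) cells to the excluded rest.

    Each excluded node takes the weight-summed majority label among its
    labeled neighbors (ties: smallest cluster id).  Nodes with no labeled
    neighbor take the label of the nearest labeled node by unweighted
    breadth-first hop distance (ties: smallest node id, then smallest label).
    Unlabeled connected components with no labeled node at all become fresh
    clusters, one per component.  Core labels are never changed.
    """
    excluded = set(int(i) for i in excluded)
    core = {int(k): int(v) for k, v in core_labels.items()}
    if set(core) | excluded != set(range(g.n_nodes)) or set(core) & excluded:
        raise ClusteringError("core labels plus excluded nodes must partition the graph")
    adj = g.adjacency()
    out = dict(core)

    # pass 1: weighted majority over labeled (core) neighbors
    pending = []
    for node in sorted(excluded):
        votes: dict[int, float] = {}
        for nbr, w in adj[node]:
            if nbr in core:
                votes[core[nbr]] = votes.get(core[nbr], 0.0) + w
        if votes:
            out[node] = min(votes, key=lambda lab: (-votes[lab], lab))
        else:
            pending.append(node)

    # pass 2: nearest core node by BFS hops through the full graph
    still_pending = []
    for node in pending:
        seen = {node}
        frontier = deque([(node, 0)])
        found: list[tuple[int, int]] = []
        found_depth = None
        while frontier:
            cur, d = frontier.popleft()
            if found_depth is not None and d > found_depth:
                break
            if cur in core:
                found.append((cur, core[cur]))
                found_depth = d
                continue
            for nbr, _ in adj[cur]:
                if nbr not in seen:
                    seen.add(nbr)
                    frontier.append((nbr, d + 1))
        if found:
            found.sort()
            out[node] = found[0][1]
        else:
            still_pending.append(node)

    # pass 3: components with no labeled node form new clusters
    if still_pending:
        next_label = max(out.values(), default=-1) + 1
        assigned: dict[int, int] = {}
        for node in sorted(still_pending):
            if node in assigned:
                continue
            comp = {node}
            frontier = deque([node])
            while frontier:
                cur = frontier.popleft()
                for nbr, _ in adj[cur]:
                    if nbr not in comp and nbr in still_pending:
                        comp.add(nbr)
                        frontier.append(nbr)
            for member in comp:
                assigned[member] = next_label
            next_label += 1
        out.update(assigned)
    return out
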