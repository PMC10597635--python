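"""Binary quadratic models for balanced graph min-cut and minimum vertex cover.

A binary quadratic model (BQM, a.k.a. QUBO) is an energy function over binary
variables ``x_i in {0, 1}``::

    E(x) = offset + sum_i h_i x_i + sum_{i<j} J_ij x_i x_j

Two encodings are built here:

* **Balanced min-cut.**  Each edge of a weighted graph contributes
  ``w_ij (x_i + x_j - 2 x_i x_j)``: a penalty of ``w_ij`` whenever its two
  endpoints land in different clusters, and zero otherwise.  To exclude the
  trivial all-in-one-cluster minimizer, a balance constraint
  ``(sum_i x_i - |V|/2)^2`` is added with multiplier ``gamma``.  Expanding the
  square and reducing ``x^2 -> x`` (binary idempotence) gives linear terms
  ``gamma (1 - |V|)`` per variable and ``+2 gamma`` on every variable pair; the
  state-independent constant ``gamma |V|^2 / 4`` is dropped, so reported
  energies are comparable only within one model.

* **Minimum vertex cover (MVC).**  Selecting vertex ``i`` costs ``x_i``; an
  uncovered edge (both endpoints unselected) pays
  ``gamma (1 - x_i - x_j + x_i x_j)``.  For ``gamma > 1`` every ground state is
  a true cover, since covering an edge by selecting one endpoint is always
  cheaper than leaving it uncovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import BQMError
from .snn_graph import SNNGraph

__all__ = [
    "BinaryQuadraticModel",
    "MinCutParams",
    "MvcParams",
    "build_mincut_bqm",
    "build_mvc_bqm",
    "mincut_family",
    "mvc_family",
    "energy",
    "cut_weight",
    "default_mincut_gamma",
]


@dataclass
class BinaryQuadraticModel:
    """Energy function ``offset + sum h_i x_i + sum_{i<j} J_ij x_i x_j``.

    ``quadratic`` keys are unordered variable pairs stored as ``(i, j)`` with
    ``i < j``; both endpoints must be distinct and below ``n_vars``.
    """

    n_vars: int
    linear: dict[int, float] = field(default_factory=dict)
    quadratic: dict[tuple[int, int], float] = field(default_factory=dict)
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise BQMError("a BQM needs at least one variable")
        for i in self.linear:
            if not 0 <= i < self.n_vars:
                raise BQMError(f"linear index {i} out of range for {self.n_vars} variables")
        for i, j in self.quadratic:
            if i == j:
                raise BQMError(f"quadratic key ({i}, {j}) has identical endpoints")
            if not (0 <= i < j < self.n_vars):
                raise BQMError(f"quadratic key ({i}, {j}) is not an ordered in-range pair")

    # -- evaluation ---------------------------------------------------------

    def energy(self, x) -> float:
        """Energy of a single binary state ``x`` (length ``n_vars``)."""
        x = _as_binary(x, self.n_vars)
        e = self.offset
        for i, h in self.linear.items():
            e += h * x[i]
        for (i, j), q in self.quadratic.items():
            e += q * x[i] * x[j]
        return float(e)

    def energies(self, states: np.ndarray) -> np.ndarray:
        """Vectorized energies of an ``(m, n_vars)`` array of binary states."""
        states = np.asarray(states, dtype=np.float64)
        h, j_upper, offset = self.to_dense()
        return offset + states @ h + np.einsum("mi,ij,mj->m", states, j_upper, states)

    def to_dense(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Return ``(h, J_upper, offset)`` with ``J_upper`` strictly upper triangular."""
        h = np.zeros(self.n_vars)
        for i, v in self.linear.items():
            h[i] = v
        j = np.zeros((self.n_vars, self.n_vars))
        for (a, b), v in self.quadratic.items():
            j[a, b] = v
        return h, j, float(self.offset)

    def coefficient_range(self) -> tuple[float, float]:
        """(max absolute coefficient, min nonzero absolute coefficient)."""
        vals = np.array(
            [abs(v) for v in self.linear.values()] + [abs(v) for v in self.quadratic.values()]
        )
        vals = vals[vals > 0]
        if vals.size == 0:
            return 1.0, 1.0
        return float(vals.max()), float(vals.min())

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_vars": self.n_vars,
                "linear": {str(i): v for i, v in self.linear.items()},
                "quadratic": [[i, j, v] for (i, j), v in sorted(self.quadratic.items())],
                "offset": self.offset,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BinaryQuadraticModel":
        d = json.loads(text)
        return cls(
            n_vars=int(d["n_vars"]),
            linear={int(i): float(v) for i, v in d["linear"].items()},
            quadratic={(int(i), int(j)): float(v) for i, j, v in d["quadratic"]},
            offset=float(d["offset"]),
        )


@dataclass(frozen=True)
class MinCutParams:
    """Balance multiplier for the min-cut objective; ``gamma >= 0``."""

    gamma: float
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise BQMError("min-cut gamma must be non-negative")


@dataclass(frozen=True)
class MvcParams:
    """Uncovered-edge multiplier for the vertex-cover objective; ``gamma > 0``."""

    gamma: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise BQMError("MVC gamma must be positive")


def _as_binary(x, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (n,):
        raise BQMError(f"state has shape {x.shape}, expected ({n},)")
    if not np.isin(x, (0, 1)).all():
        raise BQMError("state entries must be 0 or 1")
    return x.astype(np.int64)


def build_mincut_bqm(g: SNNGraph, p: MinCutParams) -> BinaryQuadraticModel:
    """Balanced min-cut BQM of ``g``.

    Linear terms are the (weighted) degree plus ``gamma (1 - |V|)``; quadratic
    terms are ``-2 w_ij`` on edges plus ``+2 gamma`` on every unordered pair.
    With ``weighted=False`` all edges count with weight 1 regardless of the
    stored Jaccard weights.
    """
    if g.n_nodes < 2:
        raise BQMError("min-cut needs at least two nodes")
    n = g.n_nodes
    gamma = p.gamma
    linear = {i: gamma * (1.0 - n) for i in range(n)}
    quadratic: dict[tuple[int, int], float] = {}
    if gamma != 0.0:
        for i in range(n):
            for j in range(i + 1, n):
                quadratic[(i, j)] = 2.0 * gamma
    for (i, j), w in g.weights.items():
        w_eff = w if p.weighted else 1.0
        linear[i] += w_eff
        linear[j] += w_eff
        quadratic[(i, j)] = quadratic.get((i, j), 0.0) - 2.0 * w_eff
    return BinaryQuadraticModel(n_vars=n, linear=linear, quadratic=quadratic, offset=0.0)


def build_mvc_bqm(g: SNNGraph, p: MvcParams) -> BinaryQuadraticModel:
    """Minimum-vertex-cover BQM of ``g``; edges are treated as unweighted."""
    if len(g.weights) < 1:
        raise BQMError("vertex cover needs at least one edge")
    gamma = p.gamma
    n = g.n_nodes
    linear = {i: 1.0 for i in range(n)}
    quadratic: dict[tuple[int, int], float] = {}
    for i, j in g.weights:
        linear[i] -= gamma
        linear[j] -= gamma
        quadratic[(i, j)] = gamma
    return BinaryQuadraticModel(
        n_vars=n, linear=linear, quadratic=quadratic, offset=gamma * len(g.weights)
    )


def mincut_family(g: SNNGraph, weighted: bool = True):
    """Return ``gamma -> BQM`` for ``g`` with the gamma-independent structure
    (edge list, weighted degrees) computed once, mirroring a fixed annealer
    embedding whose coefficients are re-tuned between runs."""
    n = g.n_nodes
    wdeg = np.zeros(n)
    edge_items = sorted(g.weights.items())
    for (i, j), w in edge_items:
        w_eff = w if weighted else 1.0
        wdeg[i] += w_eff
        wdeg[j] += w_eff

    def at_gamma(gamma: float) -> BinaryQuadraticModel:
        p = MinCutParams(gamma=gamma, weighted=weighted)
        linear = {i: wdeg[i] + p.gamma * (1.0 - n) for i in range(n)}
        quadratic: dict[tuple[int, int], float] = {}
        if p.gamma != 0.0:
            for i in range(n):
                for j in range(i + 1, n):
                    quadratic[(i, j)] = 2.0 * p.gamma
        for (i, j), w in edge_items:
            w_eff = w if weighted else 1.0
            quadratic[(i, j)] = quadratic.get((i, j), 0.0) - 2.0 * w_eff
        return BinaryQuadraticModel(n_vars=n, linear=linear, quadratic=quadratic)

    return at_gamma


def mvc_family(g: SNNGraph):
    """Return ``gamma -> BQM`` reusing the fixed cover structure of ``g``."""
    deg = g.degrees()
    edges = sorted(g.weights)

    def at_gamma(gamma: float) -> BinaryQuadraticModel:
        p = MvcParams(gamma=gamma)
        linear = {i: 1.0 - p.gamma * deg[i] for i in range(g.n_nodes)}
        quadratic = {(i, j): p.gamma for i, j in edges}
        return BinaryQuadraticModel(
            n_vars=g.n_nodes, linear=linear, quadratic=quadratic, offset=p.gamma * len(edges)
        )

    return at_gamma


def energy(bqm: BinaryQuadraticModel, x) -> float:
    """Energy of binary state ``x`` under ``bqm`` (module-level convenience)."""
    return bqm.energy(x)


def cut_weight(g: SNNGraph, x, weighted: bool = True) -> float:
    """Total weight of edges whose endpoints fall on different sides of ``x``."""
    x = _as_binary(x, g.n_nodes)
    total = 0.0
    for (i, j), w in g.weights.items():
        if x[i] != x[j]:
            total += w if weighted else 1.0
    return total


def default_mincut_gamma(g: SNNGraph) -> float:
    """Default balance multiplier ``2 W / |V|^2`` (W = total edge weight).

    The balance penalty of a maximally unbalanced state is then ~W/2, the same
    order as the worst possible cut, so neither term dominates a priori.
    """
    n = g.n_nodes
    if n < 2:
        return 0.0
    return 2.0 * g.total_weight() / float(n * n)
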