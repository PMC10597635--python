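"""Synthetic scRNA-seq count matrices with planted, optionally overlapping clusters.

The generator draws a log-normal baseline expression level per gene, gives
each cluster a block of marker genes boosted by ``exp(logfc)``, optionally
blends the mean profiles of paired clusters to create "closely related
subtypes", and samples negative-binomial counts around the cluster means with
a moderate log-normal library-size factor per cell.  This is the minimal noise
model under which SNN-graph clustering is a meaningful exercise; it does not
emulate dropout zero-inflation, batch effects or doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import SimulationError
from .expression_io import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate", "closely_related_preset"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-cluster count generator.

    ``overlap`` in [0, 1) pulls paired clusters' mean profiles toward their
    common average: 0 leaves them untouched, values near 1 make the pair
    indistinguishable.  Clusters are paired (0,1), (2,3), ...; with odd
    ``k_clusters`` the last cluster stays distinct — for k=5 this yields two
    pairs of near-duplicate subtypes plus one separate cluster.
    """

    n_cells: int = 500
    n_genes: int = 1000
    k_clusters: int = 3
    proportions: list[float] | None = None
    marker_genes_per_cluster: int = 25
    logfc: float = 2.0
    dispersion: float = 2.0
    overlap: float = 0.0
    baseline_mean: float = 0.5
    cell_size_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters < 2:
            raise SimulationError("need at least two clusters")
        if self.proportions is None:
            self.proportions = [1.0 / self.k_clusters] * self.k_clusters
        if len(self.proportions) != self.k_clusters:
            raise SimulationError("proportions length must equal k_clusters")
        if abs(sum(self.proportions) - 1.0) > 1e-9 or min(self.proportions) <= 0:
            raise SimulationError("proportions must be positive and sum to 1")
        if not (0.0 <= self.overlap < 1.0):
            raise SimulationError("overlap must lie in [0, 1)")
        if self.logfc <= 0 or self.dispersion <= 0:
            raise SimulationError("logfc and dispersion must be positive")
        if self.k_clusters * self.marker_genes_per_cluster > self.n_genes:
            raise SimulationError(
                f"cannot allocate {self.k_clusters} x {self.marker_genes_per_cluster} "
                f"marker genes among {self.n_genes} genes"
            )


def largest_remainder_counts(proportions, n: int) -> np.ndarray:
    """Integer allocation of ``n`` items to ``proportions`` by largest remainder
    (remainder ties broken by lower index)."""
    p = np.asarray(proportions, dtype=np.float64)
    ideal = p * n
    base = np.floor(ideal).astype(np.int64)
    short = n - base.sum()
    order = sorted(range(len(p)), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in order[: int(short)]:
        base[i] += 1
    return base


def cluster_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """(k, n_genes) expected expression per cluster, before cell-size scaling."""
    base = spec.baseline_mean * rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    mu = np.tile(base, (spec.k_clusters, 1))
    m = spec.marker_genes_per_cluster
    for c in range(spec.k_clusters):
        mu[c, c * m : (c + 1) * m] *= np.exp(spec.logfc)
    if spec.overlap > 0:
        blend = spec.overlap / 2.0
        for c in range(0, spec.k_clusters - 1, 2):
            a, b = mu[c].copy(), mu[c + 1].copy()
            mu[c] = (1 - blend) * a + blend * b
            mu[c + 1] = blend * a + (1 - blend) * b
    return mu


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw a count matrix and its planted labels; fixed seed, fixed output."""
    rng = np.random.default_rng(spec.seed)
    mu = cluster_means(spec, rng)
    sizes = largest_remainder_counts(spec.proportions, spec.n_cells)
    labels = np.repeat(np.arange(spec.k_clusters), sizes)

    size_factor = rng.lognormal(mean=0.0, sigma=spec.cell_size_sd, size=spec.n_cells)
    mean = mu[labels] * size_factor[:, None]
    # negative binomial with size r: variance = m + m^2 / r
    r = spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=[f"cell_{i:05d}" for i in range(spec.n_cells)],
        gene_ids=[f"gene_{j:05d}" for j in range(spec.n_genes)],
    )
    return matrix, labels


def closely_related_preset(n_cells: int = 500, seed: int = 0) -> SyntheticSpec:
    """Five cell types with two near-duplicate pairs and one distinct type.

    Mimics a population containing two pairs of hard-to-separate endothelial
    subtypes plus one clearly separated type — the regime where a single
    clustering answer is ambiguous and the low-energy solution ensemble is
    informative.
    """
    return SyntheticSpec(
        n_cells=n_cells,
        n_genes=1000,
        k_clusters=5,
        overlap=0.5,
        seed=seed,
    )
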