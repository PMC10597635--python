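# Methods

This note documents the models implemented in `annealclust`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Graph representation

Cells are embedded by library-size normalization (counts scaled to 10,000 per
cell — the conventional unit that removes sequencing-depth differences),
`log1p`, and PCA (default 20 components, full SVD). Each cell's neighborhood
is its k nearest Euclidean neighbors (default k = 20) plus itself; an edge
joins two cells when the Jaccard similarity of their neighborhoods exceeds the
prune threshold (default 1/15, the customary SNN pruning value), and that
similarity is the edge weight. Distance ties are broken by lower cell index,
and each principal component's sign is fixed so its largest-magnitude loading
is positive; without these two conventions the graph could differ between BLAS
builds. Cells left without edges stay in the graph and end up as singleton
clusters.

An alternative edge weighting (`mode="binary-expression"`) uses the Jaccard
similarity of the two cells' sets of expressed (nonzero-count) genes instead
of their neighbor sets. The neighbor-set mode is the default because it is the
standard SNN construction; the binarized-expression variant is kept as an
option since detection patterns, rather than neighborhood overlap, are
occasionally the similarity of interest and the two give different graphs on
sparse data.

## Balanced min-cut BQM

A bipartition is a binary state `x`; its energy is

    E(x) = Σ_{(i,j)∈E} w_ij (x_i + x_j − 2 x_i x_j)
         + γ ( Σ_i (1 − |V|) x_i + Σ_{i<j} 2 x_i x_j ).

The edge term pays `w_ij` exactly when an edge is cut. The γ term is the
expansion of the balance constraint `(Σ_i x_i − |V|/2)²` after reducing
`x² → x` (idempotence of binaries) and dropping the state-independent constant
`γ|V|²/4`. Consequences of that convention:

* energies satisfy `E(x) = cut(x) + γ(Σx − |V|/2)² − γ|V|²/4` (verified
  exhaustively in the test suite), are invariant under complement `x ↔ 1−x`,
  and are comparable only within one BQM;
* for odd `|V|` the balance target `|V|/2` is a half-integer; the best
  achievable balance energy sits `γ/4` above the even case. No rounding is
  applied.

Edge weights enter the cut term by default (the Jaccard coefficients are the
quadratic couplings); `weighted=False` recovers the plain unit-weight
objective. Whether γ should also scale the weighted-degree linear terms is a
genuine modelling choice; here γ multiplies only the balance expansion, which
keeps the cut objective and the constraint separable and makes the identity
above exact.

Default γ is `2W/|V|²` (W = total edge weight), re-derived per subgraph during
recursion: a maximally unbalanced state then pays a balance penalty of order
W/2, the same magnitude as the worst cut, so neither term swamps the other.
`tune_gamma` scans candidates on a fixed model structure (only γ-scaled
coefficients change, the analogue of re-tuning an annealer without
re-embedding) and scores each candidate's best sampled state by relative cut
weight plus relative imbalance, rejecting candidates whose ground state is
degenerate (one empty side); ties go to the smaller γ.

## Samplers

* `exact_sample` enumerates all `2^n` states (refused above 20 variables) and
  is the oracle in tests.
* `sa_sample` runs independent Metropolis single-bit-flip anneals (default
  500 reads × 1000 sweeps) over a geometric inverse-temperature ladder.
  The schedule is auto-scaled from the coefficient range — hot end
  `β = 1/max|coeff|` (most flips accepted), cold end `β = 1000/min|coeff|`
  (fully frozen) — so defaults adapt to the problem without hand tuning.
  Each read is seeded as `seed + read`, making results independent of read
  scheduling and bitwise reproducible.
* Any other backend can be plugged in through the `Sampler` contract; returned
  sample sets are validated (sorted energies, distinct aggregated states,
  energies recomputed from states) and a dead backend must raise, never fall
  back silently.

Sample sets order ties deterministically: energy, then lexicographic state.

## Recursive bipartitioning and stopping

Each recursion node samples its subgraph's min-cut BQM and splits on the best
*admissible* state — both sides at least `min_size` cells (default 10, the
minimal population worth calling a cluster), after canonicalizing complements.
Disconnected subgraphs are split along connected components before any
sampling, so zero-cut components can never be merged. A node becomes a leaf
when it is too small, too deep (default max depth 10), or the split is not
confident. Two confidence signals are consulted:

* the energy variance of the most frequently sampled distinct states
  (top 5), normalized by the squared total edge weight — high variance means
  the sampler found no consensus cut;
* the relative cut weight of the chosen split, `cut/W` over the subgraph
  (threshold 0.1): a homogeneous population has no cheap balanced cut, so an
  expensive one is not a real cluster boundary.

The second signal does the day-to-day work. Calibration on the synthetic
fixtures showed why the variance alone is insufficient: annealing reads reach
near-perfect consensus on *some* balanced cut even inside a single homogeneous
population (normalized variance ~1e-6), while a graph of several true clusters
can show the *largest* variance because several genuinely different good cuts
coexist — so no variance threshold separates "keep splitting" from "stop".
Relative cut weight separates the two regimes by an order of magnitude
(measured ≤ 0.04 on structured subgraphs vs ≥ 0.22 on homogeneous ones across
seeds and overlap settings); 0.1 sits between the two bands. The variance stop
is retained for the case it does detect: wildly disagreeing low-energy states.

## Minimum vertex cover sub-sampling

The MVC objective `Σ_i x_i + γ Σ_{(i,j)∈E} (1 − x_i − x_j + x_i x_j)` treats
edges as unweighted — coverage is combinatorial, and leaving weights out keeps
the quadratic term sparse (only real edges couple), which is the point of
using a cover to shrink the problem. For γ > 1, covering an edge is always
cheaper than leaving it uncovered, so exactly sampled ground states are true
covers; the default γ = 2 adds headroom. Sweeping γ on the fixed structure
adjusts the cover size (selection cost dominates as γ → 0, the true minimum
cover is reached for large γ). Among degenerate minimum-energy states the
smallest, then lexicographically first cover is chosen.

Cells outside the cover take the weight-summed majority label of their
labeled neighbors (ties to the smallest cluster id), falling back to the
nearest labeled cell by breadth-first hop distance; unlabeled components with
no labeled cell at all become new clusters. Core labels are never changed.

## Solution ensembles

Complement canonicalization (`min(x, 1−x)` lexicographically) identifies the
two encodings of each bipartition. The ensemble substitutes each node's top
distinct admissible states one at a time — at an internal node replacing the
chosen cut, at a low-confidence leaf splitting it — and re-clusters the
affected subtree deterministically. Substituting at stopped leaves is what
surfaces "alternative subpopulation" solutions: a pair of closely related
subtypes that the main run conservatively left merged appears in the ensemble
as a split variant. Partitions are deduplicated up to cluster renumbering;
each carries the substituted state's energy under its node's BQM (energies
across nodes are therefore on different scales) and its occurrence count.
Scores are the mean silhouette (singleton clusters scored 0 by convention)
and the Rand index, reported raw with the adjusted variant alongside; the
k-means baseline runs Lloyd's algorithm once per restart to expose the local
minima a single-answer method samples from.

## Synthetic data

The generator plants `k` clusters in negative-binomial counts: gene baselines
are log-normal (σ = 1, mean scaled by `baseline_mean = 0.5`, giving realistic
sparse counts at 1000 genes), each cluster boosts its block of 25 marker genes
by `exp(logfc)` (default logfc = 2), per-cell library sizes vary log-normally
(σ = 0.2), and counts are drawn with dispersion 2 (variance μ + μ²/2,
moderately overdispersed). The `overlap` parameter blends the mean profiles of
paired clusters (0,1), (2,3), … toward their common average — `overlap=0`
leaves them distinct, values near 1 make a pair indistinguishable; with odd
`k` the last cluster stays separate. The five-type preset (`overlap=0.5`)
emulates a population with two near-duplicate subtype pairs plus one distinct
type: the regime where single-answer clustering is ambiguous and the ensemble
is informative. Cells are emitted in cluster blocks with proportions allocated
by largest remainder.

What the generator does *not* emulate: zero-inflated dropout, batch effects,
doublets, continuous differentiation trajectories, or realistic gene-gene
correlation. Passing recovery tests on this data shows the optimization
pipeline recovers planted discrete structure through NB noise; it does not
certify performance on real tissue, where curated annotations remain the
benchmark.

## Problem sizes and determinism

Test and reference computations run at desk scale: 200-250 cells, 1000 genes,
graphs of a few hundred nodes, exact enumeration up to 12-20 variables,
SA at 100-500 reads. These sizes keep every check exhaustive or
well-replicated while the full suite runs in minutes; the pipeline itself has
no hard size limit (SA cost grows as reads × sweeps × |V| per node).

All randomness flows from explicit integer seeds: the generator and k-means
use one `numpy` Generator per call, each SA read derives its stream from
`seed + read`, and each recursion node derives its seed from the base seed and
a CRC of its cell subset, so identical subtrees resample identically and every
result in this repository reproduces bitwise under a fixed seed.

## Known limitations

* Recursive bipartitioning cannot produce a k-way split whose every two-way
  coarsening is inadmissible; `min_size` interacts with this.
* Ensemble energies are not comparable across recursion nodes (documented
  above); ranking across nodes is by raw energy regardless.
* The simulated annealer is a classical stand-in: it reproduces the sampling
  *interface* of an annealer (many low-energy reads with occurrence counts),
  not quantum-tunneling search dynamics or hardware noise.
* `stopping_confidence` is exposed and tested, but on SNN graphs of the kind
  studied here its discriminative power is weak (see calibration discussion);
  the relative-cut stop is the operative default.
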