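"""Samplers producing low-energy states of a binary quadratic model.

Three routes are provided:

* :func:`exact_sample` — full enumeration of all ``2^n`` states, the ground
  truth oracle for small models;
* :func:`sa_sample` — multi-read Metropolis simulated annealing over a
  geometric inverse-temperature ladder, the classical stand-in for a quantum
  annealer at realistic sizes;
* :class:`Sampler` — the abstract backend contract any solver (including a
  remote annealer client) must satisfy; results are validated against the
  :class:`SampleSet` invariants, and backend unavailability must surface as a
  typed error rather than a silent fallback.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .errors import SamplerError, SampleSetValidationError
from .qubo_models import BinaryQuadraticModel

__all__ = [
    "SampleSet",
    "Sampler",
    "ExactSampler",
    "SimulatedAnnealingSampler",
    "exact_sample",
    "sa_sample",
    "validate_sampleset",
]

EXACT_LIMIT = 20


@dataclass
class SampleSet:
    """Distinct sampled binary states with energies and occurrence counts.

    Rows are sorted by non-decreasing energy, ties broken lexicographically by
    state, and each distinct state appears exactly once with its occurrences
    aggregated.
    """

    states: np.ndarray  # (m, n_vars) uint8
    energies: np.ndarray  # (m,)
    occurrences: np.ndarray  # (m,) positive ints

    @classmethod
    def from_samples(
        cls, states: np.ndarray, bqm: BinaryQuadraticModel, occurrences=None
    ) -> "SampleSet":
        """Aggregate raw reads into a valid SampleSet; energies are computed
        from the states (never trusted from the backend)."""
        states = np.ascontiguousarray(np.asarray(states, dtype=np.uint8))
        if states.ndim != 2 or states.shape[1] != bqm.n_vars:
            raise SamplerError("states must be a 2-D array matching the BQM's variables")
        if occurrences is None:
            occurrences = np.ones(states.shape[0], dtype=np.int64)
        occurrences = np.asarray(occurrences, dtype=np.int64)
        uniq, inverse = np.unique(states, axis=0, return_inverse=True)
        occ = np.zeros(uniq.shape[0], dtype=np.int64)
        np.add.at(occ, inverse, occurrences)
        energies = bqm.energies(uniq)
        order = sorted(range(uniq.shape[0]), key=lambda r: (energies[r], tuple(uniq[r])))
        order = np.asarray(order, dtype=np.int64)
        return cls(states=uniq[order], energies=energies[order], occurrences=occ[order])

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def n_vars(self) -> int:
        return self.states.shape[1]

    def best(self) -> tuple[np.ndarray, float]:
        """Lowest-energy state and its energy."""
        return self.states[0], float(self.energies[0])

    def by_frequency(self, top_m: int) -> "SampleSet":
        """The ``top_m`` most frequently occurring distinct states (ties broken
        by lower energy, then lexicographically)."""
        order = sorted(
            range(len(self)),
            key=lambda r: (-self.occurrences[r], self.energies[r], tuple(self.states[r])),
        )[:top_m]
        keep = np.asarray(sorted(order), dtype=np.int64)
        return SampleSet(
            states=self.states[keep],
            energies=self.energies[keep],
            occurrences=self.occurrences[keep],
        )

    def to_jsonl(self) -> str:
        lines = []
        for s, e, o in zip(self.states, self.energies, self.occurrences):
            lines.append(
                json.dumps(
                    {"state": "".join(str(int(b)) for b in s), "energy": float(e),
                     "occurrences": int(o)}
                )
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str, bqm: BinaryQuadraticModel) -> "SampleSet":
        states, occ = [], []
        for line in text.strip().splitlines():
            d = json.loads(line)
            states.append([int(c) for c in d["state"]])
            occ.append(d["occurrences"])
        return cls.from_samples(np.asarray(states, dtype=np.uint8), bqm, occ)


def validate_sampleset(ss: SampleSet, bqm: BinaryQuadraticModel | None = None) -> SampleSet:
    """Enforce the SampleSet invariants; raise on any violation.

    Used to vet third-party backends: lists must be parallel, states binary
    and distinct, energies sorted non-decreasing and (when the model is given)
    exactly reproducible from the states.
    """
    if not (len(ss.states) == len(ss.energies) == len(ss.occurrences)):
        raise SampleSetValidationError("states/energies/occurrences lengths differ")
    if len(ss) == 0:
        raise SampleSetValidationError("empty sample set")
    if not np.isin(ss.states, (0, 1)).all():
        raise SampleSetValidationError("non-binary state entries")
    if (np.asarray(ss.occurrences) < 1).any():
        raise SampleSetValidationError("occurrence counts must be positive")
    if np.any(np.diff(ss.energies) < 0):
        raise SampleSetValidationError("energies are not sorted non-decreasing")
    if np.unique(ss.states, axis=0).shape[0] != len(ss):
        raise SampleSetValidationError("duplicate states present")
    if bqm is not None:
        recomputed = bqm.energies(ss.states)
        if not np.allclose(recomputed, ss.energies, rtol=0, atol=1e-9):
            raise SampleSetValidationError("stored energies drift from recomputation")
    return ss


def exact_sample(bqm: BinaryQuadraticModel, limit: int = EXACT_LIMIT) -> SampleSet:
    """Enumerate all ``2^n`` states of ``bqm``, each with occurrence 1.

    Refuses models above ``limit`` variables (default 20); use the simulated
    annealing sampler beyond that.
    """
    n = bqm.n_vars
    if n > limit:
        raise SamplerError(
            f"exact enumeration limited to {limit} variables (got {n}); "
            "use the simulated-annealing sampler instead"
        )
    codes = np.arange(2**n, dtype=np.uint64)
    # x[0] is the most significant bit so enumeration order is lexicographic
    shifts = np.arange(n - 1, -1, -1, dtype=np.uint64)
    states = ((codes[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    return SampleSet.from_samples(states, bqm)


def _auto_beta_range(bqm: BinaryQuadraticModel) -> tuple[float, float]:
    """Problem-adaptive schedule: hot enough to accept flips across the largest
    coefficient, cold enough to freeze the smallest one."""
    cmax, cmin = bqm.coefficient_range()
    return 1.0 / cmax, 1000.0 / cmin


def sa_sample(
    bqm: BinaryQuadraticModel,
    num_reads: int = 500,
    sweeps: int = 1000,
    beta_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> SampleSet:
    """Simulated annealing: ``num_reads`` independent single-bit-flip anneals.

    Each read runs ``sweeps`` full passes over the variables with the inverse
    temperature rising geometrically from ``beta_range[0]`` to
    ``beta_range[1]`` (auto-scaled from the coefficient range when omitted).
    Identical seeds give identical results.
    """
    from ._sa_core import sa_anneal

    if num_reads < 1:
        raise SamplerError("num_reads must be >= 1")
    if sweeps < 1:
        raise SamplerError("sweeps must be >= 1")
    if beta_range is None:
        beta_range = _auto_beta_range(bqm)
    lo, hi = beta_range
    if not (0 < lo < hi):
        raise SamplerError(f"invalid beta range {beta_range}: need 0 < low < high")
    h, j_upper, _ = bqm.to_dense()
    j_sym = j_upper + j_upper.T
    betas = np.geomspace(lo, hi, sweeps)
    states = sa_anneal(j_sym, h, betas, int(num_reads), int(seed) % (2**31 - 1))
    return SampleSet.from_samples(states.astype(np.uint8), bqm)


class Sampler(ABC):
    """Backend contract: turn a BQM into a valid :class:`SampleSet`.

    Implementations must return results passing :func:`validate_sampleset`;
    an unreachable backend raises :class:`~annealclust.errors.BackendUnavailableError`.
    """

    @abstractmethod
    def sample(self, bqm: BinaryQuadraticModel, num_reads: int, seed: int = 0) -> SampleSet:
        ...


class ExactSampler(Sampler):
    """Brute-force enumeration backend (deterministic; ignores reads/seed)."""

    def __init__(self, limit: int = EXACT_LIMIT):
        self.limit = limit

    def sample(self, bqm, num_reads: int = 1, seed: int = 0) -> SampleSet:
        return validate_sampleset(exact_sample(bqm, limit=self.limit), bqm)


class SimulatedAnnealingSampler(Sampler):
    """Metropolis annealing backend with a fixed sweep schedule."""

    def __init__(self, sweeps: int = 1000, beta_range: tuple[float, float] | None = None):
        self.sweeps = sweeps
        self.beta_range = beta_range

    def sample(self, bqm, num_reads: int = 500, seed: int = 0) -> SampleSet:
        ss = sa_sample(
            bqm, num_reads=num_reads, sweeps=self.sweeps, beta_range=self.beta_range, seed=seed
        )
        return validate_sampleset(ss, bqm)
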