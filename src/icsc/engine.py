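"""Iterative consensus spectral clustering of a connectivity-matrix ensemble.

The engine alternates between (i) a group partition obtained by spectral
clustering of the ensemble consensus matrix and (ii) per-individual
spectral partitions whose module counts are chosen to maximize agreement
(AMI) with the current group partition.  The objective is the
*consensus-cost*: the sum over individuals of the AMI between the group
and each individual partition, which the alternation drives upward until
it stabilizes.

The same engine serves two levels of analysis: individuals = subjects
(group-level modules of a cohort) and individuals = repeated scans of one
subject (subject-level modules).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .partition import (
    ConsensusMatrix,
    Modularization,
    ami,
    build_consensus,
    mean_pairwise_ami,
)
from .spectral import (
    ConnectivityMatrix,
    ScreeRange,
    elbow,
    normalized_spectrum,
    partition_from_eigenvectors,
)

__all__ = [
    "ICSCConfig",
    "ICSCResult",
    "LmaxDiagnostic",
    "consensus_cost",
    "select_individual_count",
    "run_icsc",
    "run_subject_level",
    "lmax_diagnostic",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ICSCConfig:
    """Run parameters for the iterative consensus loop.

    ``srange`` bounds every module count searched; ``cost_tolerance`` is
    the smallest consensus-cost change still treated as progress;
    ``n_restarts`` independent runs are launched (restart ``r`` reseeded
    with ``seed + r``) and the restart with the highest final
    consensus-cost is returned.
    """

    srange: ScreeRange
    cost_tolerance: float = 1e-9
    max_iterations: int = 50
    n_restarts: int = 1
    seed: int = 0
    discretization: str = "rotation"

    def __post_init__(self) -> None:
        if self.cost_tolerance < 0:
            raise ValueError("cost_tolerance must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class ICSCResult:
    """Converged state of one ICSC run (best restart, best iteration).

    ``cost_trace`` records the consensus-cost after every iteration of
    the winning restart; ``group``/``individuals`` are the best-cost
    state of that restart and ``consensus`` is rebuilt from those
    individuals, so ``consensus_cost(group, individuals)`` reproduces
    ``cost`` exactly.
    """

    group: Modularization
    individuals: tuple[Modularization, ...]
    individual_counts: tuple[int, ...]
    consensus: ConsensusMatrix
    cost: float
    cost_trace: tuple[float, ...]
    n_iterations: int
    converged: bool
    seed: int
    initial_pairwise_ami: float | None = None
    final_pairwise_ami: float | None = None
    initial_group_scan_ami: float | None = None
    final_group_scan_ami: float | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def group_count(self) -> int:
        return self.group.n_modules


@dataclass(frozen=True)
class LmaxDiagnostic:
    """Adequacy report for the upper module-count bound.

    An L_max chosen too small shows up as a pile-up of individual module
    counts at the bound; ``flagged`` is raised when the mass at L_max
    exceeds ``threshold`` of the ensemble.
    """

    histogram: dict[int, int]
    fraction_at_lmax: float
    threshold: float
    flagged: bool


def consensus_cost(
    group: Modularization, individuals: Sequence[Modularization]
) -> float:
    """Sum over individuals of AMI(group, individual); at most K."""
    if len(individuals) == 0:
        raise ValueError("need at least one individual partition")
    return float(sum(ami(group, s) for s in individuals))


def _scan_counts(
    eigenvectors: np.ndarray,
    group: Modularization,
    srange: ScreeRange,
    rng_seeds: Sequence[int],
    method: str,
) -> tuple[int, Modularization, float]:
    """Scan l in [l_min, l_max] on a cached spectrum; maximize AMI with group.

    Ties break toward the smallest count.  Returns (count, partition, ami).
    """
    best: tuple[int, Modularization, float] | None = None
    for j, l in enumerate(srange.counts()):
        part = partition_from_eigenvectors(
            eigenvectors, l, seed=rng_seeds[j], method=method
        )
        score = ami(group, part)
        if best is None or score > best[2] + 1e-12:
            best = (l, part, score)
    assert best is not None
    return best


def _child_seeds(ss: np.random.SeedSequence, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def select_individual_count(
    W: ConnectivityMatrix | np.ndarray,
    group: Modularization,
    srange: ScreeRange,
    seed: int | np.random.SeedSequence = 0,
    method: str = "rotation",
) -> tuple[int, Modularization]:
    """Choose an individual's module count by maximal agreement with the group.

    Spectrally partitions ``W`` at every count in the admissible range
    and returns the count (smallest on ties) whose partition has the
    highest AMI with the group partition, along with that partition.
    """
    _, vecs = normalized_spectrum(W)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    seeds = _child_seeds(ss, len(srange.counts()))
    count, part, _ = _scan_counts(vecs, group, srange, seeds, method)
    return count, part


def _consensus_affinity(pi: ConsensusMatrix) -> np.ndarray:
    """Consensus matrix as a clustering affinity: self-counts removed."""
    a = pi.values.astype(float).copy()
    np.fill_diagonal(a, 0.0)
    return a


def _run_once(
    ensemble: Sequence[ConnectivityMatrix],
    config: ICSCConfig,
    seed: int,
    progress: Callable[[int, float], None] | None = None,
) -> ICSCResult:
    srange = config.srange
    method = config.discretization
    K = len(ensemble)
    ls = list(srange.counts())
    root = np.random.SeedSequence(seed)
    ss_group, ss_indiv = root.spawn(2)

    # Per-individual spectra never change, and with run-level (not
    # iteration-level) seeds neither do the candidate partitions at each
    # admissible count: discretize each (individual, count) pair once and
    # let every iteration's count selection re-score the cached
    # candidates against the current group partition.
    candidates: list[list[Modularization]] = []
    indiv_seqs = ss_indiv.spawn(K)
    for k, W in enumerate(ensemble):
        _, vecs = normalized_spectrum(W)
        seeds = _child_seeds(indiv_seqs[k], len(ls))
        candidates.append(
            [
                partition_from_eigenvectors(vecs, l, seed=s, method=method)
                for l, s in zip(ls, seeds)
            ]
        )

    # Initialization: per-individual elbow on W^k picks the starting count.
    counts = [elbow(W, srange) for W in ensemble]
    individuals = [candidates[k][ls.index(c)] for k, c in enumerate(counts)]
    initial_individuals = list(individuals)

    group_seed = _child_seeds(ss_group, 1)[0]

    best: tuple[float, Modularization, list[Modularization], list[int]] | None = None
    trace: list[float] = []
    prev_cost = -np.inf
    prev_group: Modularization | None = None
    converged = False

    for it in range(config.max_iterations):
        pi = build_consensus(individuals)
        affinity = _consensus_affinity(pi)
        L = elbow(affinity, srange)
        group = partition_from_eigenvectors(
            normalized_spectrum(affinity)[1], L, seed=group_seed, method=method
        )
        if it == 0:
            # plain consensus clustering: the group of the initial
            # individual partitions, before any realignment
            initial_alignment = consensus_cost(group, individuals) / K

        new_individuals: list[Modularization] = []
        new_counts: list[int] = []
        for k in range(K):
            scores = [ami(group, cand) for cand in candidates[k]]
            j = int(np.argmax(scores))  # ties -> smallest count
            new_individuals.append(candidates[k][j])
            new_counts.append(ls[j])
        individuals = new_individuals
        counts = new_counts

        cost = consensus_cost(group, individuals)
        trace.append(cost)
        if progress is not None:
            progress(it + 1, cost)
        logger.info("iteration %d: consensus-cost %.6f", it + 1, cost)
        if best is None or cost > best[0]:
            best = (cost, group, list(individuals), list(counts))

        revisited = any(
            abs(cost - c) <= max(config.cost_tolerance, 1e-12)
            for c in trace[:-1]
        )
        if (
            abs(cost - prev_cost) < config.cost_tolerance
            or (prev_group is not None and group.equivalent_to(prev_group))
            or revisited  # deterministic map revisiting a state: a cycle
        ):
            converged = True
            break
        prev_cost = cost
        prev_group = group

    assert best is not None
    cost, group, individuals, counts = best
    result = ICSCResult(
        group=group,
        individuals=tuple(individuals),
        individual_counts=tuple(counts),
        consensus=build_consensus(individuals),
        cost=cost,
        cost_trace=tuple(trace),
        n_iterations=len(trace),
        converged=converged,
        seed=seed,
    )
    # stash initialization-state details for the subject-level wrapper
    object.__setattr__(result, "_initial_individuals", tuple(initial_individuals))
    object.__setattr__(result, "_initial_alignment", float(initial_alignment))
    return result


def run_icsc(
    ensemble: Sequence[ConnectivityMatrix],
    config: ICSCConfig,
    progress: Callable[[int, float], None] | None = None,
) -> ICSCResult:
    """Detect the consensus group partition of a connectivity-matrix ensemble.

    Runs ``config.n_restarts`` independent alternations (restart ``r``
    seeded ``config.seed + r``) and returns the restart with the highest
    final consensus-cost; within a restart the best-cost iteration is
    kept, so the reported cost is the maximum observed.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two connectivity matrices")
    n = ensemble[0].n_nodes
    for k, W in enumerate(ensemble):
        if W.n_nodes != n:
            raise ValueError(
                f"matrix {k} covers {W.n_nodes} nodes, expected {n}"
            )
    if config.srange.l_max >= n:
        raise ValueError("l_max must be smaller than the node count")

    best: ICSCResult | None = None
    for r in range(config.n_restarts):
        result = _run_once(ensemble, config, config.seed + r, progress=progress)
        logger.info(
            "restart %d: cost %.6f after %d iterations",
            r,
            result.cost,
            result.n_iterations,
        )
        if best is None or result.cost > best.cost:
            best = result
    assert best is not None
    return best


def run_subject_level(
    scans: Sequence[ConnectivityMatrix],
    config: ICSCConfig,
    progress: Callable[[int, float], None] | None = None,
) -> ICSCResult:
    """Consensus partition of repeated scans of a single subject.

    Identical engine with scans as the individuals; the group output is
    the subject-level partition.  Additionally reports the mean pairwise
    AMI among scan-level partitions at initialization and at convergence
    — the improvement the iterations buy.
    """
    if len(scans) < 2:
        raise ValueError("need at least two scans")
    result = run_icsc(scans, config, progress=progress)
    initial = getattr(result, "_initial_individuals")
    return replace(
        result,
        initial_pairwise_ami=mean_pairwise_ami(initial),
        final_pairwise_ami=mean_pairwise_ami(result.individuals),
        initial_group_scan_ami=getattr(result, "_initial_alignment"),
        final_group_scan_ami=result.cost / result.n_individuals,
    )


def lmax_diagnostic(
    individual_counts: Sequence[int],
    srange: ScreeRange,
    threshold: float = 0.1,
) -> LmaxDiagnostic:
    """Flag an upper module-count bound that truncates the count distribution.

    Mirrors the practice of raising L_max in steps until the histogram of
    individual module counts is smooth: a mass above ``threshold`` at
    L_max indicates individuals forced to a sub-optimal count.
    """
    counts = [int(c) for c in individual_counts]
    if len(counts) == 0:
        raise ValueError("need at least one individual count")
    for c in counts:
        if not (srange.l_min <= c <= srange.l_max):
            raise ValueError(f"count {c} outside [{srange.l_min}, {srange.l_max}]")
    hist = {l: 0 for l in srange.counts()}
    for c in counts:
        hist[c] += 1
    frac = hist[srange.l_max] / len(counts)
    return LmaxDiagnostic(
        histogram=hist,
        fraction_at_lmax=float(frac),
        threshold=float(threshold),
        flagged=bool(frac > threshold),
    )
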