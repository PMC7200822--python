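"""Hard partitions of a node set and the metrics that compare them.

A *modularization* assigns every node of a fixed node set to exactly one
module (community).  This module holds the partition container plus all
partition-level computations used by the consensus-clustering engine:
modular (co-assignment) matrices, the ensemble consensus matrix, AMI and
pair-counting MCC scores, Jaccard-based label matching, and node/module
purity profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = [
    "Modularization",
    "ConsensusMatrix",
    "PurityProfile",
    "to_modular_matrix",
    "build_consensus",
    "ami",
    "mcc",
    "match_labels",
    "purity",
    "mean_pairwise_ami",
]


@dataclass(frozen=True)
class Modularization:
    """A hard partition of ``n_nodes`` nodes into positively labelled modules.

    Labels are positive integers; any permutation of the labels describes
    the same partition, and every metric in this module is invariant to
    such relabelings.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("module labels must be integers")
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=True)
        if arr.min() < 1:
            raise ValueError("module labels must be positive integers")
        arr.setflags(write=False)
        object.__setattr__(self, "labels", arr)

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def module_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def canonicalized(self) -> "Modularization":
        """Relabel modules 1..L in order of first appearance."""
        _, first = np.unique(self.labels, return_index=True)
        order = self.labels[np.sort(first)]
        mapping = {int(lab): i + 1 for i, lab in enumerate(order)}
        return Modularization(np.array([mapping[int(v)] for v in self.labels]))

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def equivalent_to(self, other: "Modularization") -> bool:
        """True iff both group the nodes identically (up to relabeling)."""
        if self.n_nodes != other.n_nodes:
            return False
        return np.array_equal(
            self.canonicalized().labels, other.canonicalized().labels
        )


@dataclass(frozen=True)
class ConsensusMatrix:
    """Pairwise co-assignment counts summed over an ensemble of partitions.

    ``values[i, j]`` counts the individuals that place nodes ``i`` and
    ``j`` in the same module; the diagonal therefore equals
    ``n_individuals``.
    """

    values: np.ndarray
    n_individuals: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("consensus matrix must be square")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if v.min() < 0 or v.max() > self.n_individuals:
            raise ValueError("consensus entries must lie in [0, K]")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[0])

    def fractions(self) -> np.ndarray:
        """Co-assignment frequencies in [0, 1]."""
        return self.values.astype(float) / float(self.n_individuals)


@dataclass(frozen=True)
class PurityProfile:
    """Per-node modal-assignment stability across an ensemble.

    ``node_purity[i]`` is the fraction of individuals assigning node ``i``
    its modal (most frequent, label-matched) module ``modal_labels[i]``;
    ``module_purity`` maps each reference module label to the mean purity
    of its member nodes.
    """

    node_purity: np.ndarray
    modal_labels: np.ndarray
    module_purity: Mapping[int, float]


def _check_same_nodes(parts: Sequence[Modularization]) -> int:
    n = parts[0].n_nodes
    for idx, p in enumerate(parts):
        if p.n_nodes != n:
            raise ValueError(
                f"partition {idx} covers {p.n_nodes} nodes, expected {n}"
            )
    return n


def to_modular_matrix(s: Modularization) -> np.ndarray:
    """Binary co-assignment matrix: entry (i, j) is 1 iff labels match."""
    lab = s.labels
    return (lab[:, None] == lab[None, :]).astype(np.int64)


def build_consensus(partitions: Sequence[Modularization]) -> ConsensusMatrix:
    """Sum the modular matrices of an ensemble into a consensus matrix."""
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    _check_same_nodes(partitions)
    total = to_modular_matrix(partitions[0])
    for p in partitions[1:]:
        total = total + to_modular_matrix(p)
    return ConsensusMatrix(values=total, n_individuals=len(partitions))


def ami(s: Modularization, t: Modularization) -> float:
    """Adjusted mutual information between two partitions.

    Mutual information corrected by its expectation under the
    fixed-marginals (hypergeometric) permutation model and normalized by
    the maximum of the two partition entropies:
    ``(MI - E[MI]) / (max(H(s), H(t)) - E[MI])``.

    Degenerate convention: if both partitions consist of a single module
    they are necessarily identical and the score is 1; if exactly one is
    a single module (zero entropy) the score is 0 unless the partitions
    coincide.
    """
    _check_same_nodes((s, t))
    if s.n_modules == 1 and t.n_modules == 1:
        return 1.0
    if s.n_modules == 1 or t.n_modules == 1:
        return 1.0 if s.equivalent_to(t) else 0.0
    return float(
        adjusted_mutual_info_score(s.labels, t.labels, average_method="max")
    )


def mcc(s: Modularization, truth: Modularization) -> float:
    """Matthews correlation coefficient over unordered node pairs.

    Pairs co-assigned in both partitions are true positives, separated in
    both are true negatives, co-assigned only in ``s`` false positives and
    only in ``truth`` false negatives.  Identical partitions score 1; if
    any factor of the denominator vanishes the score is 0 by convention.
    """
    _check_same_nodes((s, truth))
    if s.equivalent_to(truth):
        return 1.0
    cont = contingency_matrix(truth.labels, s.labels).astype(np.int64)
    nij = cont
    a = nij.sum(axis=1)  # truth module sizes
    b = nij.sum(axis=0)  # s module sizes
    n = s.n_nodes

    def pairs(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    tp = pairs(nij.ravel())
    fp = pairs(b) - tp  # co-assigned in s only
    fn = pairs(a) - tp  # co-assigned in truth only
    tn = n * (n - 1) // 2 - tp - fp - fn
    factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(f == 0 for f in factors):
        return 0.0
    num = float(tp) * float(tn) - float(fp) * float(fn)
    den = float(np.sqrt(np.prod([float(f) for f in factors])))
    return num / den


def _jaccard_overlap(reference: Modularization, target: Modularization):
    cont = contingency_matrix(reference.labels, target.labels).astype(float)
    ref_sizes = cont.sum(axis=1)
    tgt_sizes = cont.sum(axis=0)
    union = ref_sizes[:, None] + tgt_sizes[None, :] - cont
    return cont / union


def match_labels(
    reference: Modularization,
    target: Modularization,
    scheme: str = "optimal",
) -> Modularization:
    """Rename target modules to the reference labels they best overlap.

    Module correspondence is established on the pairwise Jaccard-overlap
    matrix, either by an optimal one-to-one assignment (Hungarian
    algorithm, default) or greedily by descending overlap
    (``scheme="greedy"``).  Target modules left unmatched (or matched
    with zero overlap) receive fresh labels above the largest reference
    label.  The grouping of nodes is never changed, only the names of
    the groups.
    """
    _check_same_nodes((reference, target))
    jac = _jaccard_overlap(reference, target)
    ref_ids = reference.module_ids
    tgt_ids = target.module_ids

    mapping: dict[int, int] = {}
    if scheme == "optimal":
        rows, cols = linear_sum_assignment(jac, maximize=True)
        for r, c in zip(rows, cols):
            if jac[r, c] > 0.0:
                mapping[int(tgt_ids[c])] = int(ref_ids[r])
    elif scheme == "greedy":
        jac = jac.copy()
        while np.max(jac) > 0.0:
            r, c = np.unravel_index(np.argmax(jac), jac.shape)
            mapping[int(tgt_ids[c])] = int(ref_ids[r])
            jac[r, :] = -1.0
            jac[:, c] = -1.0
    else:
        raise ValueError(f"unknown matching scheme: {scheme!r}")

    fresh = int(ref_ids.max()) + 1
    for t_id in tgt_ids:
        if int(t_id) not in mapping:
            mapping[int(t_id)] = fresh
            fresh += 1
    relabeled = np.array([mapping[int(v)] for v in target.labels])
    return Modularization(relabeled)


def purity(
    reference: Modularization,
    partitions: Sequence[Modularization],
    scheme: str = "optimal",
) -> PurityProfile:
    """Node and module purity of an ensemble against a reference partition.

    Each ensemble partition is first label-matched to the reference; the
    purity of node ``i`` is then the fraction of partitions assigning it
    its modal matched label (ties broken toward the smallest label).
    Module purity averages node purity over the nodes of each reference
    module.
    """
    if len(partitions) == 0:
        raise ValueError("need at least one partition to compute purity")
    _check_same_nodes([reference, *partitions])
    n = reference.n_nodes
    k = len(partitions)
    matched = np.stack(
        [match_labels(reference, p, scheme=scheme).labels for p in partitions]
    )  # (K, n)
    node_purity = np.empty(n)
    modal = np.empty(n, dtype=np.int64)
    for i in range(n):
        vals, counts = np.unique(matched[:, i], return_counts=True)
        best = counts.max()
        modal[i] = int(vals[counts == best].min())  # tie -> smallest label
        node_purity[i] = best / k
    module_purity = {
        int(lab): float(node_purity[reference.labels == lab].mean())
        for lab in reference.module_ids
    }
    return PurityProfile(
        node_purity=node_purity, modal_labels=modal, module_purity=module_purity
    )


def mean_pairwise_ami(partitions: Sequence[Modularization]) -> float:
    """Mean AMI over all unordered pairs of an ensemble of partitions."""
    k = len(partitions)
    if k < 2:
        raise ValueError("need at least two partitions")
    vals = [
        ami(partitions[i], partitions[j])
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return float(np.mean(vals))
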