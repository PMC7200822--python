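"""Synthetic resting-state-like benchmark ensembles with known ground truth.

Builds weighted LFR-style modular networks (power-law degrees and
community sizes, mixing parameters for inter-community edges and
weights), turns them into correlation matrices by simulating correlated
time series through a Cholesky factor, corrupts the series with Rician
(magnitude-MRI) noise at a controlled SNR, and produces multi-individual
and multi-scan ensembles with controllable inter-individual membership
variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .partition import Modularization
from .spectral import ConnectivityMatrix

__all__ = [
    "LFRParams",
    "GroundTruthNetwork",
    "ScanParams",
    "EnsembleSpec",
    "generate_weighted_lfr",
    "nearest_positive_definite",
    "simulate_scan",
    "realized_snr",
    "perturb_memberships",
    "generate_group_ensemble",
    "generate_scan_ensemble",
]


@dataclass(frozen=True)
class LFRParams:
    """Weighted LFR benchmark parameters.

    Defaults reproduce a 264-region resting-state-like network: scale-free-ish
    degrees (exponent 1.13, average 25, maximum 53), heterogeneously sized
    communities (exponent 1.36, sizes 5-58) and half of each node's edges
    and strength crossing community boundaries (mu_topology = mu_weight = 0.5).
    ``min_degree`` is a hard floor; the working lower cutoff of the degree
    power law is solved from ``avg_degree``.
    """

    n_nodes: int = 264
    avg_degree: float = 25.0
    max_degree: int = 53
    min_degree: int = 1
    degree_exponent: float = 1.13
    community_size_exponent: float = 1.36
    weight_exponent: float = 1.5
    min_community: int = 5
    max_community: int = 58
    mu_topology: float = 0.5
    mu_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.min_degree <= self.avg_degree <= self.max_degree):
            raise ValueError("require min_degree <= avg_degree <= max_degree")
        if self.max_degree >= self.n_nodes:
            raise ValueError("max_degree must be below n_nodes")
        if not (0 < self.min_community <= self.max_community <= self.n_nodes):
            raise ValueError("invalid community size bounds")
        for mu in (self.mu_topology, self.mu_weight):
            if not (0.0 <= mu <= 1.0):
                raise ValueError("mixing parameters must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A weighted modular network together with its planted partition."""

    weights: np.ndarray
    truth: Modularization
    params: LFRParams | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape[0] != w.shape[1] or w.shape[0] != self.truth.n_nodes:
            raise ValueError("weights and planted partition sizes differ")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return int(self.weights.shape[0])

    @property
    def n_communities(self) -> int:
        return self.truth.n_modules


@dataclass(frozen=True)
class ScanParams:
    """Time-series simulation parameters for one scan.

    ``snr`` follows the fMRI temporal-SNR convention: mean signal
    magnitude divided by the noise standard deviation (``None`` or
    ``inf`` switches the noise off).  ``baseline`` is the mean signal
    level in units of the fluctuation standard deviation; 30 sits in the
    typical single-echo 3T cortical range.
    """

    n_timepoints: int = 1200
    snr: float | None = 100.0
    seed: int = 0
    baseline: float = 30.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        if self.snr is not None and not (self.snr > 0):
            raise ValueError("snr must be positive")


@dataclass(frozen=True)
class EnsembleSpec:
    """A multi-individual synthetic cohort specification."""

    n_individuals: int = 20
    perturb_fraction: float = 0.1
    scan_params: ScanParams = field(default_factory=ScanParams)
    lfr_params: LFRParams = field(default_factory=LFRParams)
    move_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least two individuals")
        if not (0.0 <= self.perturb_fraction <= 1.0):
            raise ValueError("perturb_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# power-law sampling helpers


def _powerlaw_probs(exponent: float, lo: int, hi: int) -> np.ndarray:
    support = np.arange(lo, hi + 1, dtype=float)
    p = support ** (-exponent)
    return p / p.sum()


def _powerlaw_mean(exponent: float, lo: int, hi: int) -> float:
    support = np.arange(lo, hi + 1, dtype=float)
    p = support ** (-exponent)
    return float((support * p).sum() / p.sum())


def _solve_lower_cutoff(params: LFRParams) -> int:
    """Smallest-|error| integer lower cutoff matching the target mean degree."""
    best, best_err = params.min_degree, math.inf
    for lo in range(params.min_degree, params.max_degree):
        err = abs(
            _powerlaw_mean(params.degree_exponent, lo, params.max_degree)
            - params.avg_degree
        )
        if err < best_err:
            best, best_err = lo, err
    return best


def _sample_degrees(params: LFRParams, rng: np.random.Generator) -> np.ndarray:
    lo = _solve_lower_cutoff(params)
    probs = _powerlaw_probs(params.degree_exponent, lo, params.max_degree)
    support = np.arange(lo, params.max_degree + 1)
    for _ in range(50):
        deg = rng.choice(support, size=params.n_nodes, p=probs)
        if abs(deg.mean() - params.avg_degree) <= 0.1 * params.avg_degree:
            break
    if deg.sum() % 2:  # need an even number of edge stubs
        i = int(np.argmax(deg < params.max_degree))
        deg[i] += 1
    return deg.astype(np.int64)


def _sample_community_sizes(
    params: LFRParams, rng: np.random.Generator, min_needed: int
) -> list[int]:
    """Power-law community sizes tiling n_nodes exactly.

    ``min_needed`` forces at least one community large enough to host the
    highest internal degree.  Oversampled mass is shaved off the largest
    communities; infeasible draws are rejected and retried.
    """
    probs = _powerlaw_probs(
        params.community_size_exponent, params.min_community, params.max_community
    )
    support = np.arange(params.min_community, params.max_community + 1)
    for _ in range(200):
        sizes: list[int] = []
        while sum(sizes) < params.n_nodes:
            sizes.append(int(rng.choice(support, p=probs)))
        excess = sum(sizes) - params.n_nodes
        sizes.sort(reverse=True)
        for j in range(len(sizes)):
            if excess == 0:
                break
            take = min(excess, sizes[j] - params.min_community)
            sizes[j] -= take
            excess -= take
        if excess != 0:
            continue
        if max(sizes) >= min_needed:
            return sizes
    raise RuntimeError("could not tile nodes with admissible community sizes")


def _match_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    forbidden_same: np.ndarray | None = None,
    max_passes: int = 60,
) -> set[tuple[int, int]]:
    """Configuration-model matching without self-loops or multi-edges.

    ``stubs`` lists one entry per half-edge.  When ``forbidden_same`` is
    given, endpoints with equal values in it may not be joined (used for
    the inter-community stage).  Conflicting pairs are re-shuffled for a
    bounded number of passes; stubborn leftovers are dropped, leaving the
    realized degrees approximate, as in standard LFR implementations.
    """
    edges: set[tuple[int, int]] = set()
    pool = np.array(stubs, dtype=np.int64)
    for _ in range(max_passes):
        if pool.size < 2:
            break
        rng.shuffle(pool)
        leftover: list[int] = []
        for a, b in zip(pool[0::2], pool[1::2]):
            i, j = (int(a), int(b)) if a < b else (int(b), int(a))
            bad = (
                i == j
                or (i, j) in edges
                or (
                    forbidden_same is not None
                    and forbidden_same[i] == forbidden_same[j]
                )
            )
            if bad:
                leftover.extend((int(a), int(b)))
            else:
                edges.add((i, j))
        if pool.size % 2:
            leftover.append(int(pool[-1]))
        if len(leftover) == pool.size:  # no progress; reshuffle won't help forever
            pool = np.array(leftover, dtype=np.int64)
            rng.shuffle(pool)
            if len(leftover) <= 2:
                break
            continue
        pool = np.array(leftover, dtype=np.int64)
    return edges


def _assign_communities(
    int_deg: np.ndarray, sizes: Sequence[int], rng: np.random.Generator
) -> np.ndarray | None:
    """Place nodes into communities so each fits its internal degree."""
    order = np.argsort(int_deg)[::-1]
    capacity = np.array(sizes, dtype=np.int64)
    comm = np.full(int_deg.size, -1, dtype=np.int64)
    sizes_arr = np.array(sizes, dtype=np.int64)
    for i in order:
        ok = np.flatnonzero((capacity > 0) & (sizes_arr - 1 >= int_deg[i]))
        if ok.size == 0:
            return None
        c = int(rng.choice(ok))
        comm[i] = c
        capacity[c] -= 1
    return comm


def _edge_weights(
    edges: Sequence[tuple[int, int]],
    membership: np.ndarray,
    degrees: np.ndarray,
    int_counts: np.ndarray,
    ext_counts: np.ndarray,
    params: LFRParams,
) -> np.ndarray:
    """Assign positive weights so node strengths follow degree^beta split mu_w.

    Each node i targets strength d_i^beta, a fraction (1 - mu_w) of it on
    intra-community edges; an edge takes the mean of its endpoints'
    per-edge shares.
    """
    n = membership.size
    strength = degrees.astype(float) ** params.weight_exponent
    with np.errstate(divide="ignore", invalid="ignore"):
        int_share = np.where(
            int_counts > 0, (1.0 - params.mu_weight) * strength / int_counts, 0.0
        )
        ext_share = np.where(
            ext_counts > 0, params.mu_weight * strength / ext_counts, 0.0
        )
    W = np.zeros((n, n))
    for i, j in edges:
        if membership[i] == membership[j]:
            w = 0.5 * (int_share[i] + int_share[j])
        else:
            w = 0.5 * (ext_share[i] + ext_share[j])
        W[i, j] = W[j, i] = w
    return W


def generate_weighted_lfr(params: LFRParams) -> GroundTruthNetwork:
    """Generate a weighted LFR-style benchmark network with a planted partition.

    Degrees are drawn from a truncated power law whose lower cutoff is
    solved from the target average; community sizes are power-law sampled
    and tiled onto the node set; each node keeps ``1 - mu_topology`` of
    its edges inside its community (configuration-model wiring within and
    across communities); weights give each node strength ``degree**beta``
    with ``1 - mu_weight`` of it internal.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    last_err: Exception | None = None
    for _attempt in range(30):
        try:
            degrees = _sample_degrees(params, rng)
            int_deg = np.rint((1.0 - params.mu_topology) * degrees).astype(np.int64)
            int_deg = np.minimum(int_deg, degrees)
            # a node can have at most (community size - 1) internal partners
            int_deg = np.minimum(int_deg, params.max_community - 1)
            sizes = _sample_community_sizes(params, rng, int(int_deg.max()) + 1)
            comm = _assign_communities(int_deg, sizes, rng)
            if comm is None:
                raise RuntimeError("community assignment infeasible")

            edges: set[tuple[int, int]] = set()
            # intra-community wiring, one configuration model per community
            for c in range(len(sizes)):
                nodes = np.flatnonzero(comm == c)
                stubs: list[int] = []
                for i in nodes:
                    stubs.extend([int(i)] * int(int_deg[i]))
                if len(stubs) % 2:  # drop one stub of the largest contributor
                    drop = max(nodes, key=lambda i: int_deg[i])
                    stubs.remove(int(drop))
                edges |= _match_stubs(np.array(stubs, dtype=np.int64), rng)

            int_counts = np.zeros(params.n_nodes, dtype=np.int64)
            for i, j in edges:
                int_counts[i] += 1
                int_counts[j] += 1
            # external stubs follow the planned split, not the internal
            # shortfall: a dropped internal stub must not leak across
            # communities (mu_t = 0 stays exactly block-diagonal)
            ext_deg = degrees - int_deg
            ext_stubs: list[int] = []
            for i in range(params.n_nodes):
                ext_stubs.extend([i] * int(ext_deg[i]))
            ext_edges = _match_stubs(
                np.array(ext_stubs, dtype=np.int64), rng, forbidden_same=comm
            )
            edges |= ext_edges

            ext_counts = np.zeros(params.n_nodes, dtype=np.int64)
            for i, j in ext_edges:
                ext_counts[i] += 1
                ext_counts[j] += 1
            realized = int_counts + ext_counts
            if realized.min() < max(params.min_degree, 1):
                raise RuntimeError("wiring left an isolated node")
            if abs(realized.mean() - params.avg_degree) > 0.1 * params.avg_degree:
                raise RuntimeError("realized average degree out of tolerance")

            W = _edge_weights(
                sorted(edges), comm, realized, int_counts, ext_counts, params
            )
            truth = Modularization(comm + 1)
            return GroundTruthNetwork(weights=W, truth=truth, params=params)
        except RuntimeError as err:  # infeasible draw; retry with fresh randomness
            last_err = err
    raise RuntimeError(f"LFR generation failed after retries: {last_err}")


# ---------------------------------------------------------------------------
# time-series simulation


def nearest_positive_definite(
    C: np.ndarray, floor: float = 1e-8
) -> np.ndarray:
    """Project a symmetric matrix onto the positive-definite cone.

    Eigenvalues below ``floor`` are raised to it and the matrix is
    reconstructed — the Frobenius-nearest symmetric PSD matrix up to the
    floor.  The floor is escalated (x10, a few times) should Cholesky
    still fail numerically.  Idempotent; an already-PD input is returned
    unchanged to within reconstruction round-off.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("input must be square")
    if np.abs(C - C.T).max() > 1e-8 * max(1.0, np.abs(C).max()):
        raise ValueError("input must be symmetric")
    C = 0.5 * (C + C.T)
    vals, vecs = np.linalg.eigh(C)
    f = floor
    for _ in range(6):
        clipped = np.maximum(vals, f)
        B = (vecs * clipped) @ vecs.T
        B = 0.5 * (B + B.T)
        try:
            np.linalg.cholesky(B)
            return B
        except np.linalg.LinAlgError:
            f *= 10.0
    raise np.linalg.LinAlgError("positive-definite projection failed")


def _rician(series: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    e1 = rng.normal(0.0, sigma, size=series.shape)
    e2 = rng.normal(0.0, sigma, size=series.shape)
    return np.sqrt((series + e1) ** 2 + e2**2)


def simulate_scan(
    net: GroundTruthNetwork, scan: ScanParams
) -> ConnectivityMatrix:
    """Simulate one scan's correlation matrix from a ground-truth network.

    Unit-variance white-noise series per node are colored by the Cholesky
    factor of the positive-definite projection of the network matrix,
    rescaled to unit marginal variance, offset by the baseline, and
    passed through the Rician magnitude channel with the noise sd set by
    the target SNR.  The output is the Pearson correlation matrix of the
    corrupted series with negatives clipped and a zero diagonal.
    """
    rng = np.random.default_rng(scan.seed)
    sigma_mat = nearest_positive_definite(net.weights)
    U = np.linalg.cholesky(sigma_mat)
    X = rng.standard_normal((net.n_nodes, scan.n_timepoints))
    Y = U @ X
    sd = np.sqrt(np.diag(sigma_mat))
    series = scan.baseline + Y / sd[:, None]
    if scan.snr is not None and np.isfinite(scan.snr):
        sigma = float(np.mean(np.abs(series))) / scan.snr
        series = _rician(series, sigma, rng)
    corr = np.corrcoef(series)
    return ConnectivityMatrix.ingest(corr)


def realized_snr(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Empirical SNR: mean clean-signal magnitude over residual noise sd."""
    return float(np.mean(np.abs(clean)) / np.std(noisy - clean))


# ---------------------------------------------------------------------------
# inter-individual variability


def _weighted_graph(weights: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(weights.shape[0]))
    ii, jj = np.nonzero(np.triu(weights, k=1))
    G.add_weighted_edges_from(
        (int(i), int(j), float(weights[i, j])) for i, j in zip(ii, jj)
    )
    return G


def _alternate_module(
    G: nx.Graph, truth: Modularization, node: int
) -> int:
    """Module (other than the node's own) maximizing its clustering coefficient
    in the subgraph induced by that module plus the node."""
    best_label, best_cc = None, -1.0
    for lab in truth.module_ids:
        if lab == truth.labels[node]:
            continue
        members = [int(i) for i in truth.members(int(lab))]
        sub = G.subgraph(members + [node])
        cc = nx.clustering(sub, nodes=[node], weight="weight")[node]
        if cc > best_cc:
            best_cc, best_label = float(cc), int(lab)
    assert best_label is not None
    return best_label


def perturb_memberships(
    net: GroundTruthNetwork,
    fraction: float,
    K: int,
    seed: int = 0,
    move_probability: float = 0.5,
) -> list[Modularization]:
    """Per-individual planted partitions with high-betweenness nodes moved.

    Nodes are ranked by weighted betweenness centrality (weights turned
    into distances by reciprocal); the top ``fraction`` are eligible to
    vary.  Independently per individual, each eligible node moves with
    ``move_probability`` to the alternate module in which its weighted
    clustering coefficient is highest.  ``fraction = 0`` returns K copies
    of the planted partition.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    n_sel = int(round(fraction * n))
    if n_sel == 0:
        return [net.truth for _ in range(K)]
    G = _weighted_graph(net.weights)
    dist = {
        (u, v): 1.0 / d["weight"] for u, v, d in G.edges(data=True)
    }
    nx.set_edge_attributes(G, dist, "distance")
    bc = nx.betweenness_centrality(G, weight="distance", normalized=True)
    ranked = sorted(bc, key=lambda i: (-bc[i], i))
    selected = ranked[:n_sel]
    alternates = {i: _alternate_module(G, net.truth, i) for i in selected}

    partitions: list[Modularization] = []
    for _k in range(K):
        labels = net.truth.labels.copy()
        for i in selected:
            if rng.random() < move_probability:
                labels[i] = alternates[i]
        partitions.append(Modularization(labels))
    return partitions


def _rewire_for_membership(
    net: GroundTruthNetwork,
    new_truth: Modularization,
    rng: np.random.Generator,
) -> GroundTruthNetwork:
    """Rewire moved nodes so their edges respect their new community.

    Each node whose label changed keeps its degree: it is reconnected to
    ``round((1 - mu_t) * degree)`` partners inside the new community and
    the remainder outside, with weights from the generator's strength
    scheme, so membership changes are visible in the connectivity itself.
    """
    params = net.params if net.params is not None else LFRParams(n_nodes=net.n_nodes)
    W = net.weights.copy()
    moved = np.flatnonzero(net.truth.labels != new_truth.labels)
    if moved.size == 0:
        return GroundTruthNetwork(weights=W, truth=new_truth, params=net.params)
    adjacency_deg = (W > 0).sum(axis=1)
    strength = adjacency_deg.astype(float) ** params.weight_exponent
    labels = new_truth.labels
    for i in moved:
        d_i = int(adjacency_deg[i])
        W[i, :] = 0.0
        W[:, i] = 0.0
        inside = np.flatnonzero((labels == labels[i]))
        inside = inside[inside != i]
        outside = np.flatnonzero(labels != labels[i])
        n_int = min(int(round((1.0 - params.mu_topology) * d_i)), inside.size)
        n_ext = min(d_i - n_int, outside.size)
        partners_in = rng.choice(inside, size=n_int, replace=False)
        partners_out = rng.choice(outside, size=n_ext, replace=False)
        share_int = (
            (1.0 - params.mu_weight) * strength[i] / n_int if n_int else 0.0
        )
        share_ext = params.mu_weight * strength[i] / n_ext if n_ext else 0.0
        for j in partners_in:
            W[i, j] = W[j, i] = share_int
        for j in partners_out:
            W[i, j] = W[j, i] = share_ext
    return GroundTruthNetwork(weights=W, truth=new_truth, params=net.params)


def generate_group_ensemble(
    spec: EnsembleSpec,
) -> tuple[list[ConnectivityMatrix], GroundTruthNetwork, list[Modularization]]:
    """Simulate a cohort of individuals sharing one planted modular structure.

    Draws the ground-truth network, perturbs memberships per individual
    (rewiring the moved nodes' edges accordingly) and simulates each
    individual's scan.  Returns the connectivity matrices, the group
    ground truth and the per-individual planted partitions.
    """
    net = generate_weighted_lfr(spec.lfr_params)
    root = np.random.SeedSequence(spec.lfr_params.seed + 10_007 * spec.scan_params.seed)
    ss_perturb, ss_rewire, ss_scans = root.spawn(3)
    truths = perturb_memberships(
        net,
        spec.perturb_fraction,
        spec.n_individuals,
        seed=int(ss_perturb.generate_state(1)[0] % (2**31 - 1)),
        move_probability=spec.move_probability,
    )
    rewire_rng = np.random.default_rng(ss_rewire)
    scan_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in ss_scans.spawn(spec.n_individuals)
    ]
    matrices: list[ConnectivityMatrix] = []
    for k in range(spec.n_individuals):
        net_k = _rewire_for_membership(net, truths[k], rewire_rng)
        matrices.append(
            simulate_scan(net_k, replace(spec.scan_params, seed=scan_seeds[k]))
        )
    return matrices, net, truths


def generate_scan_ensemble(
    net: GroundTruthNetwork, n_scans: int, scan: ScanParams
) -> list[ConnectivityMatrix]:
    """Repeated scans of one subject: same network, fresh noise per scan."""
    if n_scans < 2:
        raise ValueError("need at least two scans")
    seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(scan.seed).spawn(n_scans)
    ]
    return [simulate_scan(net, replace(scan, seed=s)) for s in seeds]
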