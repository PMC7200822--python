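"""Normalized-cut spectral clustering on dense weighted connectivity matrices.

Implements the multiclass spectral relaxation of the normalized cut-cost
(top eigenvectors of the symmetric-normalized affinity followed by
rotation-based discretization) and the scree-plot elbow used to estimate
the number of modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .partition import Modularization

__all__ = [
    "ConnectivityMatrix",
    "ScreeRange",
    "degree_matrix",
    "cut_cost",
    "normalized_spectrum",
    "partition_from_eigenvectors",
    "spectral_partition",
    "elbow",
]

SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Dense symmetric non-negative weighted connectivity over a node set.

    Use :meth:`ingest` to build one from raw data (e.g. a Pearson
    correlation matrix): it symmetrizes within tolerance, clips negative
    weights to zero and zeroes the diagonal, recording what it changed.
    """

    weights: np.ndarray
    node_ids: tuple | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(w).all():
            bad = np.argwhere(~np.isfinite(w))[0]
            raise ValueError(
                f"non-finite entry at row {bad[0]}, col {bad[1]}"
            )
        if np.abs(w - w.T).max() > SYMMETRY_TOL:
            raise ValueError(
                "matrix is asymmetric beyond tolerance "
                f"(max |W - W.T| = {np.abs(w - w.T).max():.3g})"
            )
        if w.min() < 0:
            raise ValueError(
                "negative weights; use ConnectivityMatrix.ingest to clip"
            )
        if np.abs(np.diag(w)).max() > 0:
            raise ValueError(
                "nonzero diagonal; use ConnectivityMatrix.ingest"
            )
        if self.node_ids is not None and len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length does not match matrix size")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @classmethod
    def ingest(
        cls,
        matrix: np.ndarray,
        node_ids: Sequence | None = None,
        symmetry_tol: float = SYMMETRY_TOL,
    ) -> "ConnectivityMatrix":
        """Validate and normalize a raw square matrix into a connectivity matrix.

        Symmetrizes by averaging when ``max|W - W.T| <= symmetry_tol``,
        zeroes the diagonal (correlation inputs carry 1.0 self-terms) and
        clips negative entries to zero, counting them in ``n_clipped``.
        """
        w = np.array(matrix, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(w).all():
            bad = np.argwhere(~np.isfinite(w))[0]
            raise ValueError(f"non-finite entry at row {bad[0]}, col {bad[1]}")
        asym = np.abs(w - w.T).max()
        if asym > symmetry_tol:
            raise ValueError(
                f"matrix is asymmetric beyond tolerance (max |W - W.T| = {asym:.3g})"
            )
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        n_clipped = int((w < 0).sum())
        if n_clipped:
            w = np.clip(w, 0.0, None)
        ids = tuple(node_ids) if node_ids is not None else None
        return cls(weights=w, node_ids=ids, n_clipped=n_clipped)

    @property
    def n_nodes(self) -> int:
        return int(self.weights.shape[0])


@dataclass(frozen=True)
class ScreeRange:
    """Admissible module-count range [l_min, l_max] for elbow estimation."""

    l_min: int
    l_max: int

    def __post_init__(self) -> None:
        if not (2 <= self.l_min < self.l_max):
            raise ValueError("require 2 <= l_min < l_max")

    def counts(self) -> range:
        return range(self.l_min, self.l_max + 1)


def degree_matrix(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Weighted node degrees (row sums); the diagonal of the degree matrix."""
    w = W.weights if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
    return w.sum(axis=1)


def _weights_of(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.weights
    w = np.asarray(W, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    return w


def _fix_zero_degrees(w: np.ndarray) -> np.ndarray:
    """Give isolated nodes a tiny uniform connectivity so degrees stay positive."""
    d = w.sum(axis=1)
    dead = np.flatnonzero(d <= 0)
    if dead.size == 0:
        return w
    scale = w.max()
    eps = 1e-8 * (scale if scale > 0 else 1.0)
    w = w.copy()
    for i in dead:
        w[i, :] = eps
        w[:, i] = eps
        w[i, i] = 0.0
    warnings.warn(
        f"{dead.size} zero-degree node(s) received epsilon connectivity",
        stacklevel=3,
    )
    return w


def cut_cost(W: ConnectivityMatrix | np.ndarray, s: Modularization) -> float:
    """Normalized cut-cost of a partition on a weighted network.

    Average over modules of ``1 - (x' W x) / (x' D x)``: the mean fraction
    of each module's total degree that leaves the module.  Zero iff no
    inter-module weight exists; invariant to label permutation.
    """
    w = _weights_of(W)
    if s.n_nodes != w.shape[0]:
        raise ValueError("partition and matrix cover different node sets")
    d = w.sum(axis=1)
    total = 0.0
    ids = s.module_ids
    for lab in ids:
        mask = s.labels == lab
        vol = d[mask].sum()
        if vol <= 0:
            raise ValueError(f"module {int(lab)} has zero total degree")
        within = w[np.ix_(mask, mask)].sum()
        total += 1.0 - within / vol
    return float(total / ids.size)


def normalized_spectrum(
    W: ConnectivityMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/vectors of D^{-1/2} W D^{-1/2}, sorted descending.

    Zero-degree nodes are degeneracy-handled first.  The full symmetric
    eigendecomposition is exact and fast at the dense-connectome scale
    (a few hundred nodes) this tool targets.
    """
    w = _fix_zero_degrees(_weights_of(W))
    d = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    affinity = w * inv_sqrt[:, None] * inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(affinity)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def _rotation_discretize(
    Z: np.ndarray,
    rng: np.random.Generator,
    n_init: int = 4,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Alternating rotation toward a binary indicator matrix.

    Rows of the eigenvector block are normalized to the unit sphere; a
    rotation seeded by farthest-point row selection is alternately
    refined (SVD Procrustes step) against the row-argmax discretization
    until the discretization objective stabilizes.  ``n_init`` starting
    rows are tried and the rotation with the best final objective wins —
    a single start occasionally leaves a cluster empty even on ideal
    block matrices.  Returns 0-based column indices per row.
    """
    n, L = Z.shape
    norms = np.linalg.norm(Z, axis=1)
    norms[norms == 0] = 1.0
    Zt = Z / norms[:, None]

    best_assign: np.ndarray | None = None
    best_obj = -np.inf
    for _start in range(n_init):
        # farthest-point initial rotation (deterministic given rng)
        R = np.zeros((L, L))
        R[:, 0] = Zt[int(rng.integers(n))]
        c = np.zeros(n)
        for j in range(1, L):
            c += np.abs(Zt @ R[:, j - 1])
            R[:, j] = Zt[int(np.argmin(c))]
        # orthonormalize the initial frame for a valid rotation; QR may
        # flip column signs, which would score the picked rows at -1 in
        # their own column and merge their cluster — re-align signs
        q, _ = np.linalg.qr(R)
        flip = np.sign(np.einsum("ij,ij->j", q, R))
        flip[flip == 0] = 1.0
        R = q * flip

        last_obj = 0.0
        obj = 0.0
        assign = np.argmax(Zt @ R, axis=1)
        for _ in range(max_iter):
            X = np.zeros((n, L))
            X[np.arange(n), assign] = 1.0
            U, sv, Vt = np.linalg.svd(Zt.T @ X)
            obj = sv.sum()
            R = U @ Vt
            assign = np.argmax(Zt @ R, axis=1)
            if abs(obj - last_obj) < tol:
                break
            last_obj = obj
        if obj > best_obj:
            best_obj = obj
            best_assign = assign
    assert best_assign is not None
    return best_assign


def _kmeans_discretize(Z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from sklearn.cluster import KMeans

    norms = np.linalg.norm(Z, axis=1)
    norms[norms == 0] = 1.0
    Zt = Z / norms[:, None]
    seed = int(rng.integers(2**31 - 1))
    km = KMeans(n_clusters=Z.shape[1], n_init=10, random_state=seed)
    return km.fit_predict(Zt)


def partition_from_eigenvectors(
    eigenvectors: np.ndarray,
    L: int,
    seed: int | np.random.Generator | None = 0,
    method: str = "rotation",
) -> Modularization:
    """Discretize the top-L eigenvectors into a hard partition.

    Accepts the eigenvector matrix from :func:`normalized_spectrum`
    (columns sorted by descending eigenvalue) so the decomposition can be
    cached across repeated calls with different ``L``.
    """
    n = eigenvectors.shape[0]
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > n:
        raise ValueError("L cannot exceed the number of nodes")
    if L == 1:
        return Modularization(np.ones(n, dtype=np.int64))
    rng = np.random.default_rng(seed)
    Z = eigenvectors[:, :L]
    if method == "rotation":
        assign = _rotation_discretize(Z, rng)
    elif method == "kmeans":
        assign = _kmeans_discretize(Z, rng)
    else:
        raise ValueError(f"unknown discretization method: {method!r}")
    return Modularization(assign + 1).canonicalized()


def spectral_partition(
    W: ConnectivityMatrix | np.ndarray,
    L: int,
    seed: int | np.random.Generator | None = 0,
    method: str = "rotation",
) -> Modularization:
    """Partition a weighted network into (at most) L modules.

    Multiclass spectral clustering of the normalized cut-cost: top-L
    eigenvectors of the symmetric-normalized affinity, then rotation-based
    discretization (or k-means on the row-normalized eigenvectors with
    ``method="kmeans"``).  Deterministic given ``(W, L, seed)``; invariant
    to uniform rescaling of the weights.  Degenerate geometries may leave
    fewer than L modules non-empty.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    _, vecs = normalized_spectrum(W)
    return partition_from_eigenvectors(vecs, L, seed=seed, method=method)


def _descending_eigenvalues(M: np.ndarray | ConnectivityMatrix) -> np.ndarray:
    """Scree profile of a matrix: normalized-affinity eigenvalues, descending.

    The spectrum of D^{-1/2} M D^{-1/2} carries one near-unit eigenvalue
    per well-separated module irrespective of module size, so the scree
    knee estimates the module count even when sizes are heterogeneous
    (the raw spectrum's knee tracks the largest size gap instead).
    A 1-D input is taken to be an already-computed descending profile.
    """
    if isinstance(M, ConnectivityMatrix):
        M = M.weights
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        return np.sort(M)[::-1]
    if np.abs(M - M.T).max() > SYMMETRY_TOL * max(1.0, np.abs(M).max()):
        raise ValueError("elbow expects a symmetric matrix")
    vals, _ = normalized_spectrum(M)
    return vals


def elbow(
    M: np.ndarray | ConnectivityMatrix,
    srange: ScreeRange,
    method: str = "second_difference",
) -> int:
    """Estimate the module count from the scree profile of a matrix.

    Eigenvalues are sorted descending and the point of maximum curvature
    within ``[l_min, l_max]`` is returned.  The default curvature
    estimator is the absolute discrete second difference of the profile;
    ``method="chord"`` uses the kneedle-style distance to the straight
    line joining the profile's endpoints.  Ties break toward the smaller
    count; a flat spectrum returns ``l_min`` with a warning.  Invariant
    to uniform scaling of the matrix.
    """
    lam = _descending_eigenvalues(M)
    n = lam.size
    lo = max(srange.l_min, 2)
    hi = min(srange.l_max, n - 1)
    if hi < lo:
        raise ValueError("scree range incompatible with matrix size")
    scale = np.abs(lam).max()
    if scale == 0:
        warnings.warn("all-zero spectrum; returning l_min", stacklevel=2)
        return srange.l_min
    lam = lam / scale
    idx = np.arange(lo, hi + 1)
    if method == "second_difference":
        # The knee of a descending scree is its most concave point: the
        # count just before the drop, where the signed second difference
        # lambda_{l-1} - 2 lambda_l + lambda_{l+1} is most negative.
        curv = -(lam[idx - 2] - 2.0 * lam[idx - 1] + lam[idx])
    elif method == "chord":
        x = np.arange(1, n + 1, dtype=float)
        chord = lam[0] + (lam[-1] - lam[0]) * (x - 1.0) / (n - 1.0)
        dist = chord - lam  # positive below the chord (convex knee)
        curv = dist[idx - 1]
    else:
        raise ValueError(f"unknown elbow method: {method!r}")
    cmax = float(np.max(curv))
    if cmax <= 1e-12:  # flat (or knee-free) profile within the range
        warnings.warn(
            "flat scree profile within range; returning l_min", stacklevel=2
        )
        return srange.l_min
    # near-ties (e.g. exact symmetric corners) resolve to the smaller count
    tied = np.flatnonzero(curv >= cmax - 1e-9 * max(1.0, abs(cmax)))
    return int(idx[tied[0]])
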