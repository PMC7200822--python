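"""Shared fixtures: small planted networks and scaled-down synthetic worlds.

Everything is generated programmatically at test time; module-scoped
fixtures cache the expensive objects across a file's tests.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from icsc import (
    ConnectivityMatrix,
    LFRParams,
    Modularization,
    ScanParams,
    generate_weighted_lfr,
)

#: Half-size benchmark used by trend/iteration tests to stay inside the
#: suite's time budget; same exponents and mixing as the full network.
SMALL_LFR = dict(
    n_nodes=128,
    avg_degree=16.0,
    max_degree=32,
    min_community=5,
    max_community=32,
)


def planted_block_matrix(
    sizes: tuple[int, ...],
    within: float = 1.0,
    between: float = 0.05,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> tuple[ConnectivityMatrix, Modularization]:
    """Dense weighted matrix with planted blocks and its planted partition."""
    labels = np.concatenate(
        [np.full(sz, i + 1) for i, sz in enumerate(sizes)]
    )
    same = labels[:, None] == labels[None, :]
    w = np.where(same, within, between).astype(float)
    if jitter > 0:
        assert rng is not None
        noise = rng.uniform(-jitter, jitter, size=w.shape)
        w = w + 0.5 * (noise + noise.T)
        w = np.clip(w, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix.ingest(w), Modularization(labels)


def set_partitions(n: int, max_blocks: int | None = None):
    """All set partitions of range(n) as label vectors (restricted growth)."""
    out: list[np.ndarray] = []

    def grow(prefix: list[int], used: int) -> None:
        i = len(prefix)
        if i == n:
            out.append(np.array(prefix) + 1)
            return
        top = min(used + 1, max_blocks or n)
        for lab in range(top):
            prefix.append(lab)
            grow(prefix, max(used, lab + 1))
            prefix.pop()

    grow([], 0)
    return out


@pytest.fixture(scope="session")
def paper_net():
    """One full-scale ground-truth network at the benchmark defaults."""
    return generate_weighted_lfr(LFRParams(seed=1))


@pytest.fixture(scope="session")
def small_net():
    """Half-size ground-truth network for fast engine tests."""
    return generate_weighted_lfr(LFRParams(seed=1, **SMALL_LFR))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
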