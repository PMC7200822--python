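# Methods

## Problem and model

Functional modules of the brain — groups of regions that work together —
are usually estimated by community detection on a *single* connectivity
matrix obtained by averaging over subjects. Averaging discards the
inter-individual variability that is precisely what makes a group-level
modularization representative or not. This package implements an
iterative consensus approach for an ensemble of K dense, weighted,
non-negative connectivity matrices `W^k` over a common node set Ω
(typically Pearson correlations between regional fMRI time series, with
negative correlations clipped to zero):

* each individual k carries a hard partition `s^k` of Ω into `L^k`
  modules, obtained by multiclass spectral clustering of the normalized
  cut-cost

      cut-cost(X) = (1/L) Σ_l [ 1 − (x_l' W x_l) / (x_l' D x_l) ],

  where `x_l` is the indicator of module l and `D = diag(W·1)` the
  weighted degree matrix;
* the group carries a partition `s` obtained by spectral clustering of
  the **consensus matrix** `Π = Σ_k Π^k`, where `Π^k_{ij} = 1(s^k_i =
  s^k_j)` is individual k's binary co-assignment (modular) matrix;
* the objective is the **consensus-cost** `Σ_k AMI(s, s^k)` — the summed
  adjusted mutual information between group and individual partitions —
  which the algorithm drives upward by alternating the two levels:
  rebuild Π from the individuals, re-estimate the group count `L` and
  partition `s` from Π, then re-select each individual's count `L^k`
  (and partition) as the one in `[L_min, L_max]` whose spectral
  partition agrees best (AMI) with the current group.

Module counts are estimated from the scree of eigenvalues: the elbow of
the spectrum of the symmetric-normalized affinity `D^{-1/2} M D^{-1/2}`,
restricted to `[L_min, L_max]`. AMI uses the expected mutual information
under the fixed-marginals hypergeometric model with max-entropy
normalization; two single-module partitions score 1, and a single-module
partition against anything else scores 0 unless identical.

The same engine serves two levels: individuals = subjects gives
group-level (cohort) modules; individuals = repeated scans of one
subject gives subject-level modules.

## Algorithmic choices

**Spectral clustering.** Affinity `D^{-1/2} W D^{-1/2}` (diagonal
zeroed; a correlation input's unit diagonal only rescales degrees), full
symmetric eigendecomposition (exact and fast at the few-hundred-node
scale this targets), top-L eigenvectors, rows normalized to the unit
sphere, and rotation-based discretization: a rotation initialized by
farthest-point row selection is alternately refined by an SVD Procrustes
step against the row-argmax indicator until the objective stabilizes.
Two hard-won robustness details: (i) the orthonormalized initial frame's
column signs must be re-aligned with the picked rows (a QR sign flip
otherwise scores a block's rows at −1 in their own column and merges
that block — deterministically, even on ideal inputs); (ii) four
starting rows are tried and the best final objective kept, because a
single start leaves a cluster empty on a few percent of seeds even for
ideal block matrices. k-means on the row-normalized eigenvectors is
available as `method="kmeans"`. Zero-degree nodes receive a uniform
epsilon connectivity (1e-8 × max weight) and a warning.

**Elbow.** "Maximum curvature" of the descending scree is implemented
as the most *concave* point — the argmin of the signed second difference
`λ_{l−1} − 2λ_l + λ_{l+1}` — with near-ties resolved to the smaller
count and a flat profile falling back to `L_min` with a warning. The
absolute second difference systematically lands one past the knee
whenever the informative eigenvalues decline faster than the bulk, and
the kneedle distance-to-chord variant (kept as `method="chord"`)
overshoots by several counts on these matrices. Two properties matter
and are tested: on the normalized spectrum every well-separated module
contributes one near-unit eigenvalue *irrespective of module size*, so
the knee estimates the count even with heterogeneous sizes (the raw
consensus spectrum's knee tracks the largest module-size gap instead —
a failure mode that made the loop oscillate); and the estimator is
invariant to uniform scaling of the matrix.

**The loop.** Per-individual spectra never change, and candidate
partitions at each admissible count are discretized once per restart
with run-level seeds; every iteration then only re-scores the cached
candidates against the current group. This makes each iteration cheap
and the alternation a deterministic map, so convergence — defined as an
unchanged consensus-cost (tolerance 1e-9), an unchanged group partition,
or a revisited cost (a cycle of the deterministic map) — typically
arrives in 2–10 iterations. The alternation is not provably monotone;
the best-cost state is tracked and returned. Restart r reseeds
everything with `seed + r` and the restart with the highest final cost
wins. An `L_max` set too low shows up as a pile-up of `L^k` at the
bound; `lmax_diagnostic` flags mass above 10% there.

## Synthetic benchmark

The generator emulates what resting-state preprocessing hands the
method: 264-node correlation-like matrices with planted, heterogeneous
modules.

**Weighted LFR-style network.** Degrees from a truncated power law
(exponent 1.13, maximum 53); the lower cutoff is solved from the target
average degree 25, because a power law with that exponent on [1, 53]
cannot average 25 (the nominal minimum degree of 1 is kept only as a
floor; the solved cutoff is ≈10). Community sizes from a power law
(exponent 1.36) on [5, 58], tiled exactly onto the node set with the
excess shaved off the largest draws. Each node plans `(1−μ_t)` of its
edges inside its community (μ_t = 0.5); wiring is by per-community and
global configuration models with self/multi-edge rejection, and a
dropped internal stub is *not* recycled across communities (so μ_t = 0
is exactly block-diagonal). Weights give node i strength `d_i^1.5`
with a fraction `1−μ_w` internal (μ_w = 0.5), each edge taking the mean
of its endpoints' per-edge shares; the realized ensemble-mean internal
strength fraction is within ±0.1 of target (tested). `networkx`'s LFR
generator could not satisfy this configuration (its average-degree
solver fails and it violates the maximum-degree bound), hence the
in-package implementation.

**Scans.** The network matrix is projected to the positive-definite
cone (eigenvalue floor 1e-8 — the Frobenius projection; Cholesky is
verified), its Cholesky factor colors unit-variance white-noise series
(T = 1200 by default), which are rescaled to unit marginal variance and
offset by a baseline of 30 fluctuation standard deviations — the
typical cortical temporal-SNR regime at 3 T. Rician (magnitude-MRI)
noise replaces each sample y with `sqrt((y+ε₁)² + ε₂²)`; the noise sd is
`mean(|clean series|)/SNR`, the fMRI convention in which SNR is mean
signal magnitude over noise sd. The output is the Pearson correlation
matrix of the corrupted series, negatives clipped, diagonal zeroed.
White noise suffices for the fluctuations because only the cross-node
covariance imposed by the Cholesky factor survives into the Pearson
correlation at this T; temporal autocorrelation is not modelled.

**Inter-individual variability.** Nodes ranked by weighted betweenness
centrality (distance = 1/weight); the top `fraction` are eligible to
vary. Per individual, each eligible node moves with probability 0.5 to
the alternate module in which its weighted clustering coefficient is
highest, and the moved node's edges are rewired toward its new community
(degree kept, weights from the generator's strength scheme) — a
label-only change would be invisible in the connectivity and hence
undetectable by any method. Multi-scan ensembles redraw only the noise,
keeping memberships fixed.

What a green test does establish: count and membership recovery under
the stated noise/variability model, monotone degradation with noise,
and the benefit of the iterations over plain consensus clustering.
What it does not: robustness to physiological noise structure
(cardiac/respiratory), spatial autocorrelation, atlas misregistration,
or real inter-subject anatomy — none of which the generator emulates.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `L_min, L_max` | 5, 30 | admissible module counts; 5 known resting-state systems as floor, 30 validated by the `L^k` histogram diagnostic |
| `cost_tolerance` | 1e-9 | float-safe "no change in consensus-cost" |
| `max_iterations` | 50 | hard cap (typical convergence 2–10) |
| `n_restarts` | 1 | independent runs; highest final cost wins |
| `n_timepoints` | 1200 | scan length |
| `snr` | 100 | mean signal magnitude / noise sd; `None` = noise off |
| `baseline` | 30 | signal mean in fluctuation-sd units |
| `perturb_fraction` | 0.1 | eligible membership-varying nodes |
| eigenvalue floor | 1e-8 | positive-definite projection |

## Numerical conventions

Labels are 1-based; node ids 0-based. Ties in the individual-count scan
and the elbow resolve to the smallest count; modal labels in purity to
the smallest label. Matrices are symmetrized by averaging when
`max|W−Wᵀ| ≤ 1e-8` and rejected beyond. MCC returns 0 when any
denominator factor vanishes (1 for exact identity); label matching uses
an optimal one-to-one Hungarian assignment on the module Jaccard matrix
(greedy variant available), with unmatched target modules given fresh
labels above the reference's.

## Known limitations

* The consensus-cost alternation can enter short cycles; the returned
  best state is well-defined but the trace is then not monotone.
* Exact node-level recovery in the clean limit is not guaranteed: at
  mixing 0.5 a few low-degree nodes are genuinely better placed in a
  neighboring module under the normalized cut; the ensemble consensus
  resolves them at full scale but single scans need not.
* The generator's degree/size tiling rejects infeasible draws and
  retries, so extreme parameter combinations (e.g. μ_t = 0 with maximum
  degree ≥ maximum community size) may fail after bounded retries.
* Dense eigendecomposition bounds practical problem size to a few
  thousand nodes.
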