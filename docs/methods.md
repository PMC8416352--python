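# Methods

## Problem and model

`fcmvc` clusters subjects by their resting-state functional connectivity
(FC) while simultaneously selecting *which* brain regions carry each
clustering. The data are per-subject ROI×ROI Pearson correlation
matrices R_i (p ROIs, unit diagonal, symmetric). The latent structure
has two levels:

* a partition of the p ROIs into **views** (subnetworks), drawn from a
  Chinese restaurant process (CRP) with concentration `alpha_view`;
* within each view v of dimension d_v, a partition of the N subjects
  into **clusters**, drawn from a CRP with concentration
  `alpha_cluster`.

Given its cluster k, a subject's scatter submatrix on the view's ROIs,
S_i^(v) = ν · R_i[v, v], is modeled as Wishart_{d_v}(ν, Σ_{v,k}). The
cluster scale Σ_{v,k} carries a conjugate inverse-Wishart prior
IW(ν₀, Ψ₀) with ν₀ = d_v + `nu0_offset` and
Ψ₀ = `psi0_scale` · (ν₀ − d_v − 1) · I, so the prior mean scale is
`psi0_scale` · I — matched to whitened correlation matrices, whose
population mean is the identity. Both CRP concentrations default to 1.

Integrating Σ out gives the closed-form cluster marginal likelihood
implemented in `cluster_log_marginal` (checked in the tests against
one-dimensional adaptive quadrature and a 10⁶-draw Monte-Carlo average
in two dimensions, and via the conjugate posterior-predictive
identity).

### Scoring partitions

The joint model evaluates the *full* p×p scatter under a Wishart whose
scale is block-diagonal in the view partition. That density factorizes
into per-view conjugate integrals times a per-subject base measure
(the |S_i|, Γ_p and 2-power factors) that does not depend on the
partition. The search objective therefore uses the block-factorized
cluster term

    M0(v,k) = (ν₀/2)log|Ψ₀| − log Γ_d(ν₀/2) + log Γ_d(ν_m/2)
              − (ν_m/2)log|Ψ_m| + (m ν d/2) log 2,

with ν_m = ν₀ + mν and Ψ_m = Ψ₀ + Σᵢ S_i, summed over view-clusters and
added to the two CRP prior terms. Composing *standalone* per-view
Wishart marginals instead would implicitly discard the off-block
statistics of every split and drive the optimizer to single-ROI views
regardless of the data; within a fixed view the two forms give
identical subject-reassignment decisions, so the distinction matters
only when ROIs move between views.

## Pre-processing

* **Regularization** (`regularize_correlation`): R → (R + εI)/(1+ε)
  with ε = 0.05, i.e. a small diagonal load followed by re-conversion
  to correlation form; every eigenvalue maps to (λ+ε)/(1+ε) > 0.
* **Whitening** (`fit_whitening` / `apply_whitening`): W = R̄^{−1/2},
  the symmetric inverse square root of a reference sample mean
  correlation matrix, computed by eigendecomposition; each subject
  matrix becomes the correlation normalization of W R_i W. W is the
  unique symmetric linear map sending the reference mean to the
  identity, which removes between-subnetwork correlation on average
  while preserving within-subnetwork structure. Eigenvalues of R̄ are
  floored at `jitter` (default 1e-6) rather than shifted, so a
  well-conditioned mean is inverted exactly and the invariant
  W R̄ W = I holds to machine precision; only degenerate directions are
  repaired. The per-subject rescaling to unit diagonal keeps the
  outputs in correlation form so the downstream ν-scaling stays
  meaningful. The reference may be the dataset itself
  ("self-whitening") or another dataset (whitening validation data
  with the discovery mean); `reference_label` records which.
* Order is fixed: whiten first, then regularize, then scale by ν.

The Wishart degrees of freedom ν are not identified from a correlation
matrix alone; the package takes ν as data provenance (number of fMRI
volumes minus one, e.g. 239 for a 240-volume acquisition), overridable
everywhere. No effective-dof correction for temporal autocorrelation
is applied; if the true effective ν is smaller, cluster likelihood
ratios are overconfident but rankings are typically preserved.

## Inference

Greedy MAP coordinate ascent (`_engine.GreedySearch`), restarted from
many random initializations (CRP draws for both partitions):

1. **Subject sweep** — per view, each subject is removed and
   reassigned to the argmax over existing clusters (CRP weight m_k)
   and a new cluster (weight `alpha_cluster`) of CRP weight ×
   posterior-predictive marginal.
2. **ROI sweep** — each ROI is tentatively moved to every other view
   and to a new singleton view, scoring only the affected views with
   cluster assignments frozen (a new view starts as one cluster); the
   best strictly improving move is accepted and followed by a subject
   sweep on the affected views.

Sweeps alternate until a full pass changes nothing or `max_sweeps`
(default 50) is reached. Accepted moves never decrease the score, so
the score trace is monotone. Ties keep the incumbent; among
non-incumbent ties the lowest id wins — runs are deterministic given
the seed. Views larger than ν − 1 ROIs are rejected during ROI moves
(the Wishart density is undefined there). Sufficient statistics
(scatter sums, log-determinant sums) are maintained incrementally and
verified against from-scratch recomputation in the tests.

**Model selection** (`select_model`): rank the multistart models by
score, keep the top ten, compute pairwise ARI of their ROI view
partitions, find the max-ARI pair and keep its higher-scoring member —
a stability heuristic preferring solutions that recur across restarts.
`fit_multistart` defaults to 100 restarts (the full-scale analysis
used 1,000; desk-scale tests use 10).

The final model relabels views in ascending order of their number of
subject clusters and clusters within a view in descending order of
size (`pipeline.relabel_model`), the reporting convention used
throughout.

## Out-of-sample classification

A new subject is whitened (with either its own dataset's mean or the
discovery mean), regularized, restricted to the view's ROIs and scaled
to a scatter S. Scores are the CRP-predictive

    score_k   = log m_k + [marginal(stats_k ∪ S) − marginal(stats_k)]
    score_NEW = log alpha_cluster + marginal({S}),

and the argmax wins; `NEW` is the nonparametric "open a new cluster"
outcome. Because every candidate shares the same per-observation
factors, the standalone and block-factorized marginals give identical
argmax decisions here. The same rule applied to empty discovery
clusters would assign them weight log 0; clusters are carried with
their fitted member counts, and genuinely novel patterns fall to NEW.

**Traveling-subject agreement** (`ts_agreement_test`): per subject,
the number of scan indices (of three) whose cluster labels agree
between two sites; the statistic is the mean over subjects. The null
shuffles which subject's site-B label triple is paired with which
site-A subject (subject-level shuffling is the only unit that
preserves within-subject scan dependence);
p = (1 + #{perm ≥ obs})/(n_perm + 1). This add-one convention is valid
but conservative when the discrete statistic ties with permuted
values, so the null p-distribution is super-uniform with atoms rather
than exactly uniform; the tests assert both a seeded uniformity check
and the seed-robust validity bound P(p ≤ α) ≤ α.

## Post-hoc statistics

* Cluster×diagnosis contingency tables with a minimum cluster size of
  10 (smaller clusters are dropped before testing); disorder-wise
  (columns sum to 1) and cluster-wise (rows sum to 1) proportions both
  emitted.
* Pearson χ² with **no continuity correction** — required to reproduce
  the published pairwise p = 0.069 — and Cramér's
  V = sqrt(χ²/(N·(min(r,c)−1))).
* Kruskal–Wallis with tie correction for ordinal/continuous indices.
* Cohen's d per within-view edge with the pooled-SD denominator;
  |d| > 0.8 flags an edge, and "commonly important" edges are the
  intersection of flags of one cluster against every other. d is
  computed on the whitened, regularized correlations (the space the
  clustering saw); pass raw data to screen raw correlations.
* Classical (Torgerson) MDS of cluster-center mean matrices: Frobenius
  distances, double centering B = −½ J D² J, top-2 eigenpairs, first
  nonzero loading of each axis made positive; the continuum axis is
  the OLS line through a chosen subset of embedded centers.
* The per-view association test is χ² on the filtered cluster×diagnosis
  table with Bonferroni correction across views; the selected view
  minimizes the omnibus p.

## Baselines

* **FC-based multiple clustering**: the correlation matrix is
  vectorized into its p(p−1)/2 upper-triangular entries (Fisher
  z-transformed by default, which approximately Gaussianizes
  correlations), features are partitioned into views by the same CRP
  engine, and per-view subject clusters use independent per-feature
  Gaussian likelihoods with a conjugate normal–inverse-gamma prior
  (μ₀ = 0, κ₀ = 0.01, a₀ = 1, b₀ = 0.1 — weak, centered, unit-scale,
  suited to z-transformed correlations). The Wishart and Gaussian
  engines share the partition-search core and its bookkeeping tests.
* **Supervised pairwise classification**: for every diagnosis pair,
  the larger class is subsampled to the smaller, in-sample
  probabilities come from leave-one-out cross-validation of an
  elastic-net logistic regression (saga solver, l1_ratio 0.5), the
  refit model scores everyone else, and per-subject marginal
  probabilities average p_i(j,k) over k ≠ j; the argmax label is
  assigned (ties to the lexicographically first label).

## Synthetic data

The generator (`synthetic`) emulates the study conditions the pipeline
is meant to face: N subjects, p ROIs split into views, per-view
cluster-specific Wishart scatters, assembled block-diagonally in a
randomized ROI order (recorded, so recovery cannot exploit
contiguity) and normalized to correlation form. Cluster scales are
correlation normalizations of B_k B_kᵀ + I with d×2 loadings of SD δ;
one scalar controls separation and δ = 0 plants no structure.
Optional confounds: a rank-one cross-view coupling
M_c = I + c·uuᵀ (u the uniform unit vector) applied as
M_c R M_cᵀ before re-normalization, and a per-site linear transform
A_s. Diagnoses are uniform by default or linked to one view's
clusters with a configurable link strength, which gives the discovery
pipeline a planted diagnosis-associated view to find.

Default desk-scale regime, used by the tests and the acceptance
script: two views of 4 ROIs with 2 and 3 clusters, δ = 1.5, ν = 200,
N = 120 (200 for whitening/classification measurements), 10 restarts.
These sizes were chosen so a full multistart fit takes about a second
while keeping the regime inside the fitted ranges reported for the
real data (views of 2–25 ROIs, ≥ 3 clusters).

What the generator does *not* emulate: BOLD time series and their
autocorrelation (ν is exact by construction here, approximate in real
data), motion artifacts, heavy-tailed deviations from Wishart
sampling, and realistic anatomical covariance. Passing recovery tests
therefore show correctness of the inference machinery under the
model's own assumptions, not robustness to their violation.

## Numerical choices

* Symmetry/diagonal validation tolerance 1e-10; matrices symmetrized
  on construction.
* Whitening eigenvalue floor 1e-6 (see above).
* Greedy tie tolerance 1e-10; ROI moves require improvement > 1e-9.
* Incremental-vs-recomputed score agreement asserted at 1e-6.
* Multivariate gamma values are cached per (view-dimension, cluster
  size); log-determinants use `slogdet` (batched where possible).
* Degenerate inputs: empty clusters contribute marginal 0; empty views
  are pruned; an empty validation dataset classifies to an empty
  summary; Kruskal–Wallis on all-identical observations returns H = 0,
  p = 1 by convention.
* Seeds: every randomized entry point takes one integer seed; child
  seeds derive via `numpy.random.SeedSequence` and stay below 2³¹.

## Known limitations

* ν is treated as known; misspecification rescales likelihoods.
* The greedy search finds local optima; restarts are the only escape
  mechanism (the Gaussian baseline in particular needs ~20 restarts on
  the planted-blocks fixture to escape merged-view optima).
* No confound regression (age, sex, site) on the matrices themselves —
  element-wise residualization would break positive definiteness; site
  effects are addressed only through the choice of whitening
  reference, and harmonization methods are out of scope.
* Correlation matrices are not exactly Wishart-distributed (they are
  scaled to unit diagonal); the model treats ν·R as Wishart, which is
  the same approximation the analysis it reimplements makes.
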