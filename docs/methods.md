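# Methods

## Model

`wjsdm` estimates *differential networks*: the entrywise differences
Δ^(k) = Θ^(k2) − Θ^(k1) between the precision (inverse covariance)
matrices of two sample groups, jointly over K expression platforms.
Nonzero off-diagonals of Δ^(k) are rewired conditional dependencies —
gene pairs whose partial correlation changes between the two states.

Expression in each group/platform is modelled as nonparanormal: each
gene's marginal is an unknown strictly monotone transform of a latent
Gaussian coordinate, so the latent precision matrix still encodes
conditional independence. The estimator never fits the marginal
transforms; it only needs the latent correlation, recovered from
Kendall's tau through the sine map sin(π/2·τ).

### Covariance estimation under dropout

An entry is *observed* iff it is finite and nonzero; exact zeros emulate
scRNA-seq dropout (the convention is configurable through
`zeros_as_missing`). Kendall's tau for a gene pair is computed only over
sample pairs in which both genes are observed and is normalized by
n_ij(n_ij − 1), where n_ij counts jointly observed samples. Degenerate
pairs (n_ij ≤ 1) return τ = 0 — maximal ignorance — and ties contribute
sign(0) = 0. Because only ranks of observed values enter, the estimate is
bit-identical under strictly increasing marginal transforms (tested).

The sine-transformed matrix need not be positive semidefinite; a
projection clips negative eigenvalues at zero and rescales symmetrically
to restore the unit diagonal (a congruence, so PSD is preserved). A ridge
of 1e−8·I is added before optimization for numerical headroom.

### Loss and penalty

The smooth loss is the D-trace loss summed over platforms,

    L(Δ; S1, S2) = ¼(⟨S1Δ, ΔS2⟩ + ⟨S2Δ, ΔS1⟩) − ⟨Δ, S1 − S2⟩,

whose gradient is ½(S1ΔS2 + S2ΔS1) − (S1 − S2) and whose population
minimizer is the true precision difference — no individual precision
matrix is ever estimated. The penalty is a weighted group bridge

    P(Δ) = Σ_ij W_ij · sqrt( Σ_k τ_ij^(k) |Δ_ij^(k)| ),

with two weight layers:

* **DE pair weights** τ_ij = 1 − (1 − r_i)(1 − r_j), where r_i = 1 − p_i
  from a two-sided Wilcoxon rank-sum test per gene and platform
  (normal approximation with tie correction, no continuity correction;
  an alternative capped −log10 p mapping is available but off by
  default). The Wilcoxon test uses all recorded values including zeros:
  in dropout data part of the DE signal lives in the zero rates.
* **Prior weights** W_ij = w_g (default 0.3) for known interactions,
  1 for same-pathway pairs, w_f (default 10) across pathways — known
  interactions are cheap to rewire, cross-pathway pairs expensive.

The square root couples the K platforms per edge, encouraging shared
sparsity patterns while still allowing platform-specific edges. Diagonal
entries of Δ are penalized like any entry; only off-diagonals count as
edges (support threshold 1e−8, shared package-wide).

### Optimization

The concave square root is handled by local linear approximation (LLA).
Round 0 uses plain weights φ = τ (the tangent is undefined at the zero
start); later rounds use

    φ_ij^(k) = τ_ij^(k) / (2·sqrt(max(Σ_k τ_ij^(k)|Δ̂_ij^(k)|, ε))),

with floor ε = 1e−8. Each round solves K independent weighted-lasso
D-trace subproblems by accelerated proximal gradient: step size
1/(‖S1‖₂·‖S2‖₂) (an exact Lipschitz bound for the gradient), halving
backtracking as a safeguard, Nesterov momentum with restart whenever the
objective would increase, so the accepted objective sequence is
monotone. The prox is entrywise soft-thresholding followed by
symmetrization. The full penalized objective is recomputed after every
outer round and must be nonincreasing (violation aborts the fit);
the outer loop stops after 5 rounds (default) or when the relative
objective change drops below the inner tolerance (1e−5 default; one
stopping knob serves both loops). Per-iteration cost is O(Kp³): only
matrix products of p×p matrices appear in the hot loop.

`lambda_max` returns the smallest λ at which the all-zero network is
stationary for the convex round-0 problem:
max_k max_ij |S^(k1) − S^(k2)|_ij / (τ_ij W_ij) over penalized entries.
Entries with zero penalty weight (τ_ij W_ij = 0) can never be forced to
zero; they are excluded from the bound and reported separately. Read
λ_max as a grid upper bound: the concave LLA refinement prunes harder
than the convex stage, so at λ somewhat below λ_max the *refined* network
can legitimately be empty even though the convex stage is not — this is
the thresholding nature of bridge-type penalties, not a solver failure.

### Model selection (StARS)

For each λ on a descending grid the model is refit on N = 20 subsamples
(drawn without replacement within each group, size
b = min(⌊10√n⌋, n − 1)); covariances and DE weights are recomputed per
subsample so the whole procedure is honestly resampled. Edge selection
frequencies θ give instabilities 2θ(1 − θ), averaged over off-diagonal
pairs and platforms; after monotonization along decreasing λ, the
smallest λ whose monotonized instability stays within β = 0.05 is
selected (densest stable model). If nothing qualifies the largest grid
value is returned with a warning. N, b, and β are the method's canonical
defaults; how K platforms enter the instability is a design choice here
(per-platform frequencies, pooled by averaging).

## Synthetic data generator

The generator defines the study conditions; its defaults are the
reference protocol: p = 100 genes, K = 3 platforms, three pathways of
0.4p genes with 0.2p genes shared between pathways 2 and 3, a scale-free
(preferential attachment, one edge per arriving node — tree-like)
support per pathway, 10% differential edges per pathway with 3× sampling
weight for edges touching the DE gene set (30% of genes), 10% of the
differential set platform-specific, differential edges realized half as
deletions and half as additions, off-diagonal weights uniform on
±[0.5, 1.0], diagonals set to row absolute sums + 0.1 (strict diagonal
dominance, hence positive definiteness) then rescaled to unit diagonal.
The state-1 skeleton is shared across platforms; "addition" edges are
absent from state 1 everywhere and appear in state 2 only on platforms
where they are differential. Expression is multivariate normal with
covariance Θ⁻¹, group-2 means shifted by 0.8 on DE genes (enough for the
rank-sum test to have high power at n = 100), and entries zeroed
independently with probability τ (0.6 default), matching the estimator's
missingness convention. The prior network samples a fraction δ of the
union of the six true supports.

Two caveats. First, the per-state unit-diagonal rescaling slightly
perturbs off-diagonals adjacent to differential nodes, so the support of
the exact difference Θ^(2) − Θ^(1) is a superset of the designed
differential edges (still within pathways); evaluation scores against
the exact difference. Second, the generator draws genuinely Gaussian
data with missing-completely-at-random dropout — it does not emulate
negative-binomial counts, zero inflation correlated with expression
level, batch effects, or platform-specific marginals. Passing tests
demonstrate correct recovery under the model's own assumptions, not
robustness to everything real scRNA-seq data can do.

## Evaluation

TPR and FPR pool counts over platforms and unordered pairs (i < j) at
the shared 1e−8 support threshold; zero denominators yield NaN rather
than 0. Performance curves trace (FPR, TPR) along a descending λ grid
with warm starts; areas are trapezoidal with (0,0) and (1,1) anchors.
Hub genes are ranked by total degree across platforms, ties broken
lexicographically by gene identifier, with per-platform degrees reported
in `a|b|c` form.

The packaged recovery study runs at a reduced scale chosen to keep the
full pipeline cheap while leaving the qualitative structure intact:
p = 50, K = 2, n = 200, missing rate 0.2, prior rate 0.5, 10 (tests) or
5 (acceptance script) seeds, 15-point λ grids spanning
[λ_max/100, λ_max].

## Numerical choices and limitations

* Missingness convention: exact zero or NaN means unobserved,
  applied uniformly (configurable); bulk data without dropout should set
  `zeros_as_missing=False` if zeros are real measurements.
* All tolerances: inner APG 1e−5 relative change (500 iterations max),
  5 LLA rounds, LLA floor 1e−8, support threshold 1e−8, PSD tolerance
  −1e−8.
* The O(n²) pairwise tau computation is exact (integer-valued sums in
  float64, so results are bit-reproducible and exactly symmetric) and
  adequate at the package's target scales (n ≤ ~500).
* Gene universes are intersected at the I/O boundary; all matrices are
  indexed by gene identifier there, never by position.
* The solver does not constrain Δ to be a difference of positive
  definite matrices (not required: any symmetric matrix qualifies).
* Wilcoxon DE levels use the asymptotic normal approximation, which is
  crude below ~8 samples per group.
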