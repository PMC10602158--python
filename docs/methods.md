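# Methods

## The model

The object of study is a non-negative association matrix `X` whose rows are
(signed components of) traits and whose columns are CKD risk variants; entry
`X[t, v]` is the magnitude of the standardized effect β = B/SE of variant
`v` on trait `t`. Non-negative matrix factorization decomposes
`X ≈ H·W` with `H` (rows × K) holding trait loadings and `W` (K × variants)
holding variant weights, all entries ≥ 0. Because both factors are
non-negative, a variant can carry weight in several clusters at once — the
clustering is soft and overlapping, which is the point: a pleiotropic
variant participates in every pathway it touches.

### Sign handling

β is signed but NMF input cannot be. The default transform splits each trait
into a `trait|+` row holding `max(β, 0)` and a `trait|−` row holding
`max(−β, 0)`, dropping empty components. This loses nothing: the signed
vector is exactly `(+row) − (−row)` (a tested invariant), and after
factorization each trait's direction within a cluster is read off as the
sign of whichever component carries the larger loading. `clip` (zero the
negatives) and `abs` modes are provided for sensitivity analysis. Split mode
means the factorized matrix can have more rows than there are distinct
traits; summaries therefore report both counts.

### Filters

Selection rules run in a fixed order — gender-specific studies, study
n < 100, kidney-function traits (case-insensitive patterns seeded with
"chronic kidney", "glomerular filtration", "eGFR", "CKD"), p ≥ 1e-6, and
finally traits left with fewer than five distinct variants. The last rule
runs after the others because its trigger depends on what they removed;
removal counts are exact and conserved (removed + retained = input). The
five-variant floor is exposed as a sweep utility over 2..15 rather than an
automated chooser — it is a sensitivity knob, not an optimized quantity.

### LD proxies and allele alignment

Associations observed on proxy variants are attributed to lead variants at
r² ≥ 0.6; a proxy claimed by several leads goes to the one with the highest
r² (ties to input order). Effects are re-expressed on the
kidney-function-decreasing allele: direct match kept, other-allele match
sign-flipped, unambiguous strand flips (e.g. A/G vs T/C) complemented, and
strand-ambiguous A/T and C/G variants without a direct match rejected — the
four ambiguity cases are enumerated in tests.

## Factorization engine

The reference algorithm is Lee–Seung multiplicative updates for the
Frobenius loss,

    H ← H ⊙ (X Wᵀ) ⊘ (H W Wᵀ + ε),  W ← W ⊙ (Hᵀ X) ⊘ (Hᵀ H W + ε),

with ε = 1e-10 guarding division. The objective is non-increasing at every
step (a property tested on random instances). Defaults follow the study
design: 30 random restarts, 10,000 iteration cap, and a convergence patience
of 80 — a restart stops once the relative objective change stays below
`tol = 1e-6` for 80 consecutive iterations. The lowest-error restart wins;
everything is deterministic under a seed. Scale indeterminacy (H·D, D⁻¹·W)
is resolved on demand by unit-max normalization of H's columns.

### Rank selection

For each candidate K (default 2..20) the selector runs restarts and records
four metrics: mean silhouette width of the variants (cluster labels by
argmax weight, distance 1 − cosine similarity of W columns),
best-of-restarts Frobenius error, and two consensus diagnostics (cophenetic
correlation and dispersion of the restart consensus matrix). Selection uses
the two named criteria — highest silhouette, lowest error — as a Pareto
rule; the consensus metrics are reported for diagnostics only. One
operational refinement was needed: the silhouette plateaus once extra
components merely merge or split existing clusters, so candidates within
0.01 of the best silhouette count as tied and the tie is broken by the
sharpest relative drop in reconstruction error from the previous K (the
error elbow), remaining ties by the smaller K. Without the tolerance, a
near-tie (e.g. 0.970 vs 0.969) could override a six-fold error difference.

### Bayesian NMF with ARD

As cross-validation of K, a Bayesian NMF places half-normal priors on each
component's column of H and row of W with a shared per-component relevance
scale λ_k (inverse-gamma hyperprior, a = 2, b = 0.01, closed-form update).
MAP multiplicative updates shrink irrelevant components; a component is
pruned when the maximum element of its rank-1 contribution falls below
1e-8 · max(X). Across many random starts, the modal surviving component
count estimates K. Two numerical choices matter:

- **Burn-in.** 100 plain multiplicative updates run before the prior is
  enabled. At a random start the residual is large, so the shrinkage term
  would otherwise kill every component before any of them fits the data.
- **Noise floor.** The noise variance σ² is re-estimated from the residual
  each iteration but floored at 3% of the signal power mean(X²). On
  (near-)noiseless inputs the estimated σ² collapses and with it the ARD
  pull, freezing redundant degenerate splits; the floor keeps the pressure
  on. Convergence is judged on the full MAP objective, not the data term
  alone, because the data term is flat across exactly those degenerate
  splits.

With these in place the procedure recovers planted ranks 1–4 in 10/10
seeded runs and agrees with the silhouette/error selector on noiseless
plants. Defaults keep the study-scale settings (1,000 runs, up to 200,000
iterations); tests and the acceptance script run tens of runs and tens of
thousands of iterations on small matrices, which the run-count analysis
supports.

### Cluster summaries

Per cluster, "top decile" means weight ≥ the 90th linear-interpolation
percentile of that cluster's weights (ties included); the same rule applies
to trait-component loadings, collapsed to one entry per trait with the
direction of the dominant component. Weight summaries count variants with
weight above 1e-40, a numerically-zero floor.

## Cluster-specific polygenic scores

Raw score: `score[i, k] = Σ_j W[k, j] · dosage[i, j]`, dosages counting the
kidney-function-decreasing allele (equivalent to a PLINK --score run; score
files in that format are written for interoperability). Weight variants
missing from the genotypes are imputed with the sample's mean dosage and
logged; coverage below 90% is a hard error. Standardization is per cluster,
z = (raw − mean)/SD over a stated reference cohort — the full cohort by
default, so that ancestry sub-cohorts stay on a common scale and group
shifts remain visible; per-group standardization is available by flag.
Top-decile flags mark scores at or above the reference's 90th percentile,
ties included (so slightly more than 10% under ties).

Distributional tests: Anderson–Darling composite normality (parameters
estimated; small-sample-adjusted statistic with the Stephens case-3
piecewise p-value approximation, exponent clamped beyond its validity
range), two-sided Mann–Whitney for every ancestry pair, and a fixed
operational definition of "peaks" so multimodality is testable — Gaussian
KDE with Silverman bandwidth, strict local maxima with prominence ≥ 5% of
the density maximum. A single dominant weight (≥ ~5× the rest) at an
intermediate-frequency variant produces exactly three peaks at 0/1/2 copies;
spread weights produce one.

## PheWAS

Quantitative traits: OLS with the outcome and continuous predictors
z-scored (refit standardization), so the coefficient is SD-per-SD. Binary
traits: phecode cases (≥ 2 mapped diagnostic codes; single-code samples are
controls by default, excludable by flag), logistic ML fit, OR per SD of
cPGS with Wald CI on the log-odds scale. Covariates: sex, age, first ten
PCs; continuous covariates z-scored, binary left as indicators. Traits
observed in fewer than 100 participants are dropped first and the Bonferroni
α = 0.05/(number of remaining traits) uses post-filter counts. Binary fits
additionally require 20 cases and 20 controls (configurable); separation or
non-convergence yields a flagged row with a not-evaluable p, never a silent
drop. A top NMF trait counts as replicated when its mapped PheWAS trait
passes Bonferroni with a concordant direction.

## Synthetic data

The generator emulates the study's three data layers with planted truth:

- **Association matrices.** K_true clusters; every trait/variant gets a
  strong loading on a primary cluster and sparse weaker loadings elsewhere
  (sparsity 0.7 by default, so clusters overlap without coinciding); signs
  per trait × cluster; additive Gaussian noise on the signed matrix
  (β = B/SE is approximately normal, so additive Gaussian is the natural
  perturbation; default SD 0.05, about 5% of signal). Catalog tables emit
  B and SE such that B/SE reproduces the planted β exactly, plus exactly
  the requested number of filter-rule violations (rare-trait violations are
  planted as single-association traits so row counts equal violation
  counts).
- **Cohorts.** Hardy-Weinberg genotypes per ancestry group at
  group-specific MAFs in (0, 0.5]; age, sex, and PCs simulated as
  group centroids plus isotropic noise (a flag switches to genuine PCA of
  the dosage matrix). No admixture and no LD between variants — ancestry
  inference and LD structure are out of scope, so tests passing here say
  nothing about either.
- **Phenotypes.** Quantitative: effect·z + covariate terms + Gaussian
  noise. Binary: logistic with the intercept set to the target prevalence;
  diagnostic codes emitted as (sample, code, date) triples with 2–3 codes
  per case and an occasional single code among controls, so the
  rule-of-two is exercised literally.

What the plants do **not** emulate: LD between variants (so cPGS shrinkage
questions cannot be studied), admixed individuals, longitudinal EHR
timelines, and realistic trait-name vocabularies (replication matching on
real data needs a user-supplied name map).

One calibration note: an equal-weight score over exactly 30 variants is a
lattice-valued sum, and at n = 10,000 the Anderson–Darling test detects the
discreteness even though the KDE mode count is 1. Real scores aggregate
hundreds of variants with heterogeneous weights; at ≥ ~120 variants the
simulated scores pass normality in most seeds. Tests therefore check
unimodality at 30 variants and normality at polygenic scale.

## Problem sizes

Tests and the acceptance script use reduced problem sizes chosen to keep
stochastic checks well-resolved: planted matrices of 60×100 (and 90×140 for
the nine-cluster analog), cohorts of 10,000 samples over 30 variants,
PheWAS null calibration over 200 replicates of a 100-trait phenome at
n = 250, and bNMF with 8–10 runs on 20×30 matrices. The full-scale catalog
replay (rebuilding the published 229×322 matrix from supplementary data)
requires files that are not redistributable here; the pipeline accepts such
a table unchanged via `build-matrix` when the user supplies it.

## Known limitations

- Multiplicative updates converge slowly near the optimum; best-of-restarts
  with a patience window is robust for cluster recovery but terminal
  reconstruction error on noiseless matrices is orders of magnitude above
  coordinate-descent solvers (on noisy data both plateau at the same noise
  floor, which is what the cross-check test asserts).
- The ARD noise floor (3% of signal power) caps the rank the Bayesian NMF
  can resolve: structure explaining less variance than the floor is treated
  as noise.
- The silhouette near-tie tolerance (0.01) is a heuristic; pathological
  metric profiles could still mis-rank K, which is why the rule trace is
  always recorded and the consensus diagnostics are reported.
- Phecode exclusion-range hierarchies, survival models and relatedness
  corrections are out of scope.
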