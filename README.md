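# nephroclust

Soft clustering of chronic kidney disease (CKD) risk variants, with
cluster-specific polygenic scores and phenome-wide validation.

CKD is genetically heterogeneous: hundreds of variants lower kidney function,
but they act through different pathways (urate handling, inflammation, blood
volume, body mass, ...). `nephroclust` deconstructs that heterogeneity from
public GWAS summary statistics alone. Given a table of variant–trait
associations in GWAS-Catalog dialect, it

1. **assembles a non-negative effect matrix** `X` (traits × variants):
   LD proxies (r² ≥ 0.6) are folded back onto lead variants, effects are
   aligned to the kidney-function-decreasing allele, studies that are
   gender-specific, underpowered (n < 100), non-significant (p ≥ 1e-6) or
   about kidney function itself are filtered out, traits with fewer than five
   variants are dropped, and effects are standardized to β = B/SE. Because β
   is signed, each trait is split into a `trait|+` and a `trait|−` component
   row (`max(±β, 0)`), keeping the matrix non-negative without discarding
   direction;
2. **factorizes** `X ≈ H·W` by non-negative matrix factorization
   (Lee–Seung multiplicative updates, Frobenius loss, 30 restarts), where
   `H` holds trait loadings and `W` holds variant weights for `K` overlapping
   clusters. `K` is selected over a candidate range by mean silhouette width
   (variants labelled by argmax weight, cosine distance) and Frobenius error,
   and cross-checked with a Bayesian NMF whose automatic relevance
   determination (ARD) prior prunes superfluous components;
3. **scores a genotyped cohort**: the cluster-specific polygenic score (cPGS)
   of sample *i* in cluster *k* is `Σ_j W[k,j]·dosage[i,j]`, standardized
   within cluster against a reference cohort. Departures from normality
   (Anderson–Darling), multimodality (KDE peak counting) and ancestry-group
   shifts (Mann–Whitney) are tested, and top-decile overlap across clusters
   is reported;
4. **validates clusters with a cPGS-PheWAS**: linear models for quantitative
   traits and logistic models for phecode-derived binary traits (a case
   carries ≥ 2 mapped diagnostic codes), adjusted for sex, age and genetic
   PCs, with standardized estimates, Wald 95% CIs and Bonferroni control
   (α = 0.05 / number of post-filter traits).

Restricted biobank data are replaced by a first-class synthetic-data module:
planted factor structures, Hardy-Weinberg genotypes with ancestry-specific
allele frequencies, and phenotypes generated from the cPGS with known effect
sizes, so every stage is testable against ground truth.

## Worked example

```python
import numpy as np, pandas as pd
from nephroclust import (FactorPlant, simulate_factors, select_rank, factorize,
    CohortSpec, simulate_cohort, compute_cpgs, standardize_scores)
from nephroclust.scores import count_modes

# a planted 3-cluster association matrix, 5% noise
x, truth = simulate_factors(FactorPlant(k_true=3, n_traits=60, n_variants=100,
                                        sparsity=0.7, noise_sd=0.05, seed=7))
k, metrics, _ = select_rank(x.abs(), k_range=range(2, 7), restarts=5, seed=1)
print("chosen K:", k)
print(metrics.round(3).to_string(index=False))
```

```
chosen K: 3
 K  silhouette  frobenius_error  cophenetic  dispersion
 2       0.973           94.037       1.000       1.000
 3       0.991           10.133       1.000       1.000
 4       0.910            8.695       0.998       0.920
 5       0.752            7.356       0.996       0.927
 6       0.898            5.777       0.998       0.945
```

Rank selection recovers the planted K = 3: the silhouette peaks there and the
reconstruction error collapses from 94 to 10 (the residual 10 is the planted
noise floor — `factorize(x.abs(), 3, ...)` reports the same Frobenius error).

A single dominant variant weight recreates the three-peaked score
distributions seen for real clusters: scoring a 10,000-sample Hardy-Weinberg
cohort (30 variants, MAF 0.3) with one weight of 4.6 against runners-up
≤ 0.2 gives peaks at 0, 1 and 2 copies of the top variant:

```python
spec = CohortSpec(n_samples={"ALL": 10_000},
                  maf_by_ancestry={"ALL": np.full(30, 0.3)}, n_pcs=0, seed=3)
dosages, _ = simulate_cohort(spec, [f"rs{j}" for j in range(30)])
w = np.full(30, 0.1); w[0], w[1] = 4.6, 0.2
weights = pd.DataFrame([w], index=["inflammation"], columns=dosages.columns)
table = standardize_scores(compute_cpgs(weights, dosages))
print("modes:", count_modes(table.z["inflammation"].to_numpy()))   # modes: 3
```

The same stages are available from the shell:

```sh
nephroclust run-all --out run1 --seed 42          # simulate + full pipeline
nephroclust build-matrix --assoc assoc.tsv --ld ld.tsv --risk-alleles risk.tsv
nephroclust select-rank --matrix effect_matrix.tsv --k-min 2 --k-max 20
nephroclust factorize --matrix effect_matrix.tsv --k 9 --n-init 30
nephroclust score --weights W.tsv --genotypes dosages.tsv
nephroclust phewas --scores cpgs.tsv --phenotypes pheno.tsv --covariates cov.tsv
```

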