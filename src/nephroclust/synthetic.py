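"""Synthetic inputs with planted ground truth.

Every downstream stage (matrix assembly, factorization, polygenic scoring,
PheWAS) can be exercised without restricted biobank data: this module plants
a known factor structure, emits a GWAS-catalog-style association table with
deliberate filter-rule violations, draws Hardy-Weinberg genotypes with
ancestry-specific allele frequencies, and generates phenotypes from
cluster-specific polygenic scores with known effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Unambiguous allele pairs only: strand flips of A/G, A/C, etc. are
# detectable, unlike A/T and C/G.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class FactorPlant:
    """A planted non-negative factor structure H·W with signed trait effects.

    Parameters
    ----------
    k_true : number of planted clusters.
    n_traits, n_variants : matrix dimensions (traits x variants).
    sparsity : fraction of off-cluster loadings forced to zero, in [0, 1).
    noise_sd : SD of additive Gaussian noise on the signed matrix. Effects
        enter the matrix as beta = B/SE, which is approximately standard
        normal under the null, so additive Gaussian noise is the natural
        perturbation model.
    seed : RNG seed; identical plants are bit-identical.
    """

    k_true: int
    n_traits: int
    n_variants: int
    sparsity: float = 0.7
    noise_sd: float = 0.05
    seed: int = 0
    trait_loadings: np.ndarray | None = None
    variant_weights: np.ndarray | None = None
    sign_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k_true < 1 or self.n_traits < 1 or self.n_variants < 1:
            raise ValueError("k_true, n_traits and n_variants must be positive")
        if self.k_true > min(self.n_traits, self.n_variants):
            raise ValueError(
                f"k_true={self.k_true} exceeds min(n_traits, n_variants)="
                f"{min(self.n_traits, self.n_variants)}"
            )
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _planted_factor(n_items: int, k: int, sparsity: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw a non-negative (n_items x k) factor with a primary cluster per item.

    Each item gets a strong loading on its primary cluster and, with
    probability 1 - sparsity, weaker loadings on the others, so clusters
    overlap without being identical. Returns (factor, primary labels).
    """
    labels = np.arange(n_items) % k
    rng.shuffle(labels)
    primary = rng.uniform(1.0, 3.0, size=n_items)
    factor = np.zeros((n_items, k))
    factor[np.arange(n_items), labels] = primary
    off = rng.uniform(0.0, 0.5, size=(n_items, k))
    keep = rng.random((n_items, k)) >= sparsity
    off *= keep
    off[np.arange(n_items), labels] = 0.0
    factor += off
    return factor, labels


def simulate_factors(plant: FactorPlant) -> tuple[pd.DataFrame, dict]:
    """Generate a signed trait x variant effect matrix and its ground truth.

    The signed matrix is ``sign_mask * trait_loadings @ variant_weights``
    plus Gaussian noise; ``abs()`` of it (or its sign-split form) is the
    factorization input. Returns ``(X_signed, truth)`` where ``truth`` holds
    the planted factors, per-trait/per-variant primary cluster labels and
    the sign mask.
    """
    rng = np.random.default_rng(plant.seed)
    if plant.trait_loadings is not None:
        h = np.asarray(plant.trait_loadings, dtype=float)
        trait_labels = np.argmax(h, axis=1)
    else:
        h, trait_labels = _planted_factor(plant.n_traits, plant.k_true, plant.sparsity, rng)
    if plant.variant_weights is not None:
        w = np.asarray(plant.variant_weights, dtype=float).T  # stored K x V
        variant_labels = np.argmax(w, axis=1)
        w_kv = w.T
    else:
        w_v, variant_labels = _planted_factor(plant.n_variants, plant.k_true, plant.sparsity, rng)
        w_kv = w_v.T
    if (h < 0).any() or (w_kv < 0).any():
        raise ValueError("planted loadings and weights must be non-negative")
    if plant.sign_mask is not None:
        signs = np.asarray(plant.sign_mask)
    else:
        # one direction per trait per cluster; a trait can raise one cluster's
        # outcome and lower another's
        signs = rng.choice([-1.0, 1.0], size=(h.shape[0], h.shape[1]))
    x = (signs * h) @ w_kv
    if plant.noise_sd > 0:
        x = x + rng.normal(0.0, plant.noise_sd, size=x.shape)
    traits = [f"trait_{i:03d}" for i in range(h.shape[0])]
    variants = [f"rs{1000 + j}" for j in range(w_kv.shape[1])]
    x_df = pd.DataFrame(x, index=traits, columns=variants)
    truth = {
        "trait_loadings": h,
        "variant_weights": w_kv,
        "sign_mask": signs,
        "trait_labels": trait_labels,
        "variant_labels": variant_labels,
        "k_true": h.shape[1],
        "trait_ids": traits,
        "variant_ids": variants,
    }
    return x_df, truth


_VIOLATION_RULES = ("gender_specific", "small_n", "weak_p", "rare_trait", "ckd_trait")


def simulate_catalog_table(
    plant: FactorPlant,
    violation_counts: dict[str, int] | None = None,
    min_beta: float = 1e-3,
) -> tuple[pd.DataFrame, dict]:
    """Emit a GWAS-catalog-dialect association table for a planted matrix.

    One row per nonzero planted trait-variant effect, with B and SE chosen so
    that B/SE reproduces the planted standardized effect, plus exactly the
    requested number of rows violating each filter rule. ``rare_trait``
    violations are planted as extra traits carrying a single association each,
    so the number of planted violations equals the number of rows each filter
    removes. Returns (table, truth).
    """
    violation_counts = dict(violation_counts or {})
    bad = set(violation_counts) - set(_VIOLATION_RULES)
    if bad:
        raise ValueError(f"unknown violation rules: {sorted(bad)}")
    rng = np.random.default_rng(plant.seed + 1)
    x_df, truth = simulate_factors(plant)

    rows = []
    pair_cycle = 0
    for t_i, trait in enumerate(x_df.index):
        for v_j, variant in enumerate(x_df.columns):
            beta = x_df.iat[t_i, v_j]
            if abs(beta) < min_beta:
                continue
            se = rng.uniform(0.02, 0.2)
            ea, oa = _ALLELE_PAIRS[pair_cycle % len(_ALLELE_PAIRS)]
            pair_cycle += 1
            rows.append(
                {
                    "variant_id": variant,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "trait": trait,
                    "beta": beta * se,
                    "se": se,
                    "p_value": 10.0 ** rng.uniform(-30, -7),
                    "n": int(rng.integers(5_000, 500_000)),
                    "gender_specific": False,
                    "study": f"GCST{rng.integers(100000, 999999)}",
                }
            )

    def _clean_row(trait: str, variant: str) -> dict:
        se = rng.uniform(0.02, 0.2)
        ea, oa = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS))]
        return {
            "variant_id": variant,
            "effect_allele": ea,
            "other_allele": oa,
            "trait": trait,
            "beta": rng.normal(0.0, 2.0) * se,
            "se": se,
            "p_value": 10.0 ** rng.uniform(-30, -7),
            "n": int(rng.integers(5_000, 500_000)),
            "gender_specific": False,
            "study": f"GCST{rng.integers(100000, 999999)}",
        }

    variants = list(x_df.columns)
    for i in range(violation_counts.get("gender_specific", 0)):
        row = _clean_row(f"viol_gender_{i:02d}", variants[i % len(variants)])
        row["gender_specific"] = True
        rows.append(row)
    for i in range(violation_counts.get("small_n", 0)):
        row = _clean_row(f"viol_smalln_{i:02d}", variants[i % len(variants)])
        row["n"] = int(rng.integers(10, 100))
        rows.append(row)
    for i in range(violation_counts.get("ckd_trait", 0)):
        name = ["Estimated Glomerular Filtration Rate", "Mild to moderate chronic kidney disease", "CKD stage 3"][i % 3]
        rows.append(_clean_row(name, variants[i % len(variants)]))
    for i in range(violation_counts.get("weak_p", 0)):
        row = _clean_row(f"viol_weakp_{i:02d}", variants[i % len(variants)])
        row["p_value"] = 10.0 ** rng.uniform(-5.9, -2)
        rows.append(row)
    # rare-trait violations: one association each, so one row removed apiece
    for i in range(violation_counts.get("rare_trait", 0)):
        rows.append(_clean_row(f"viol_rare_{i:02d}", variants[i % len(variants)]))

    table = pd.DataFrame(rows)
    truth["violation_counts"] = {r: violation_counts.get(r, 0) for r in _VIOLATION_RULES}
    truth["n_clean_rows"] = len(table) - sum(truth["violation_counts"].values())
    return table, truth


@dataclass
class CohortSpec:
    """Specification of a genotyped cohort with labelled ancestry groups.

    ``maf_by_ancestry`` maps each group label to a per-variant minor-allele
    frequency array (values in (0, 0.5]); ``n_samples`` maps label to group
    size. Principal components are simulated as group centroids plus
    isotropic noise unless ``pcs_from_genotypes`` requests a genuine PCA of
    the dosage matrix.
    """

    n_samples: dict[str, int]
    maf_by_ancestry: dict[str, np.ndarray]
    age_range: tuple[float, float] = (18.0, 90.0)
    sex_ratio: float = 0.5
    n_pcs: int = 10
    pcs_from_genotypes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples:
            raise ValueError("at least one ancestry group is required")
        for label, n in self.n_samples.items():
            if n < 1:
                raise ValueError(f"group {label!r} has size {n}; sizes must be >= 1")
        for label, maf in self.maf_by_ancestry.items():
            maf = np.asarray(maf, dtype=float)
            if (maf <= 0).any() or (maf > 0.5).any():
                raise ValueError(f"MAFs for group {label!r} must lie in (0, 0.5]")
            self.maf_by_ancestry[label] = maf
        missing = set(self.n_samples) - set(self.maf_by_ancestry)
        if missing:
            raise ValueError(f"no MAF vector for groups: {sorted(missing)}")


def simulate_cohort(
    spec: CohortSpec, variant_ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw Hardy-Weinberg genotype dosages and sample covariates.

    Genotypes at each variant are Binomial(2, q) within each ancestry group
    at the group's allele frequency q (HWE). Returns (dosage matrix,
    covariates); dosages count the kidney-function-decreasing allele.
    """
    rng = np.random.default_rng(spec.seed)
    n_variants = len(variant_ids)
    sample_ids, dosage_blocks, cov_rows = [], [], []
    labels = sorted(spec.n_samples)
    for g_i, label in enumerate(labels):
        n = spec.n_samples[label]
        maf = spec.maf_by_ancestry[label]
        if maf.shape[0] != n_variants:
            raise ValueError(
                f"group {label!r}: MAF vector length {maf.shape[0]} != {n_variants} variants"
            )
        dosage_blocks.append(rng.binomial(2, maf, size=(n, n_variants)).astype(float))
        ids = [f"{label}_{i:05d}" for i in range(n)]
        sample_ids.extend(ids)
        age = rng.uniform(*spec.age_range, size=n)
        sex = (rng.random(n) < spec.sex_ratio).astype(int)
        for i in range(n):
            cov_rows.append({"sample_id": ids[i], "ancestry": label, "age": age[i], "sex": sex[i]})
    dosages = pd.DataFrame(np.vstack(dosage_blocks), index=sample_ids, columns=variant_ids)
    covariates = pd.DataFrame(cov_rows).set_index("sample_id")

    if spec.n_pcs > 0:
        if spec.pcs_from_genotypes:
            from sklearn.decomposition import PCA

            centered = dosages.to_numpy() - dosages.to_numpy().mean(axis=0)
            k = min(spec.n_pcs, centered.shape[1], centered.shape[0] - 1)
            pcs = PCA(n_components=k, random_state=spec.seed).fit_transform(centered)
            if k < spec.n_pcs:
                pcs = np.hstack([pcs, np.zeros((pcs.shape[0], spec.n_pcs - k))])
        else:
            centroids = rng.normal(0.0, 3.0, size=(len(labels), spec.n_pcs))
            group_idx = np.concatenate(
                [np.full(spec.n_samples[lb], i) for i, lb in enumerate(labels)]
            )
            pcs = centroids[group_idx] + rng.normal(0.0, 1.0, size=(len(sample_ids), spec.n_pcs))
        for j in range(spec.n_pcs):
            covariates[f"PC{j + 1}"] = pcs[:, j]
    return dosages, covariates


@dataclass
class PhenotypePlant:
    """A planted phenotype driven (or not) by one cluster's polygenic score.

    ``effect_size`` is per SD of the standardized cPGS: a slope for
    quantitative traits, a log-odds increment for binary ones. Null traits
    use ``effect_size=0`` and ``target_cluster=None``.
    """

    name: str
    kind: str = "quantitative"  # or "binary"
    target_cluster: int | None = None
    effect_size: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline_prevalence: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError("kind must be 'quantitative' or 'binary'")
        if self.kind == "binary" and not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if self.target_cluster is None and self.effect_size != 0:
            raise ValueError("null traits (no target cluster) must have effect_size 0")


def simulate_phenotypes(
    cpgs_z: pd.DataFrame,
    plants: list[PhenotypePlant],
    covariates: pd.DataFrame,
    seed: int = 0,
    codes_per_case: tuple[int, ...] = (2, 3),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate phenotypes and diagnostic codes from standardized cPGS.

    Quantitative traits are ``effect_size * z + covariate terms + noise``;
    binary traits are drawn from a logistic model whose intercept matches the
    baseline prevalence. For binary traits a long (sample, code, date) table
    is emitted in which cases carry >= 2 mapped codes and a random tenth of
    controls carry exactly one, so the phecode rule of two is exercised.
    Returns (phenotype table, diagnostic-code table, code->phecode map).
    """
    rng = np.random.default_rng(seed)
    n = len(cpgs_z)
    pheno = pd.DataFrame(index=cpgs_z.index)
    dx_rows = []
    map_rows = []
    for p_i, plant in enumerate(plants):
        if plant.target_cluster is not None and not 0 <= plant.target_cluster < cpgs_z.shape[1]:
            raise ValueError(f"target_cluster {plant.target_cluster} out of range")
        z = (
            cpgs_z.iloc[:, plant.target_cluster].to_numpy()
            if plant.target_cluster is not None
            else np.zeros(n)
        )
        lin = plant.effect_size * z
        for cov, coef in plant.covariate_effects.items():
            lin = lin + coef * covariates.loc[cpgs_z.index, cov].to_numpy(dtype=float)
        if plant.kind == "quantitative":
            pheno[plant.name] = lin + rng.normal(0.0, plant.noise_sd, size=n)
        else:
            intercept = np.log(plant.baseline_prevalence / (1 - plant.baseline_prevalence))
            prob = 1.0 / (1.0 + np.exp(-(intercept + lin)))
            case = rng.random(n) < prob
            pheno[plant.name] = case.astype(int)
            phecode = f"{500 + p_i}.0"
            icd_codes = [f"ICD{p_i:02d}.{j}" for j in range(3)]
            for icd in icd_codes:
                map_rows.append({"code": icd, "phecode": phecode, "phenotype": plant.name})
            n_codes = rng.choice(codes_per_case, size=n)
            single = rng.random(n) < 0.1  # controls occasionally carry one code
            for i, sid in enumerate(cpgs_z.index):
                k = n_codes[i] if case[i] else (1 if single[i] else 0)
                for c in range(k):
                    dx_rows.append(
                        {
                            "sample_id": sid,
                            "code": icd_codes[c % len(icd_codes)],
                            "date": f"20{10 + c:02d}-01-01",
                        }
                    )
    dx = pd.DataFrame(dx_rows, columns=["sample_id", "code", "date"])
    code_map = pd.DataFrame(map_rows, columns=["code", "phecode", "phenotype"])
    return pheno, dx, code_map


def write_vcf(dosages: pd.DataFrame, path: str) -> None:
    """Write a dosage matrix as a minimal plain-text VCF with a DS field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.index)
            + "\n"
        )
        for j, vid in enumerate(dosages.columns):
            ds = "\t".join(f"{v:g}" for v in dosages.iloc[:, j])
            fh.write(f"1\t{j + 1}\t{vid}\tA\tG\t.\tPASS\t.\tDS\t{ds}\n")


def read_vcf_dosages(path: str) -> pd.DataFrame:
    """Read a DS-field VCF written by :func:`write_vcf` (samples x variants)."""
    samples: list[str] = []
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            fmt = parts[8].split(":")
            ds_idx = fmt.index("DS")
            variant_ids.append(parts[2])
            columns.append(
                np.array([float(s.split(":")[ds_idx]) for s in parts[9:]], dtype=float)
            )
    return pd.DataFrame(np.column_stack(columns) if columns else np.empty((len(samples), 0)),
                        index=samples, columns=variant_ids)
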