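import numpy as np
import pandas as pd
import pytest

from nephroclust import CohortSpec, FactorPlant, simulate_cohort, simulate_factors


@pytest.fixture(scope="session")
def planted_k3():
    """Low-noise planted K=3 matrix with truth labels (60 traits x 100 variants)."""
    plant = FactorPlant(k_true=3, n_traits=60, n_variants=100, sparsity=0.7, noise_sd=0.05, seed=7)
    x, truth = simulate_factors(plant)
    return x, truth


@pytest.fixture(scope="session")
def noiseless_k3():
    """Exact rank-3 non-negative matrix (all-positive sign mask, no noise)."""
    plant = FactorPlant(
        k_true=3, n_traits=20, n_variants=30, sparsity=0.7, noise_sd=0.0, seed=11,
        sign_mask=np.ones((20, 3)),
    )
    x, truth = simulate_factors(plant)
    return x.abs(), truth


@pytest.fixture(scope="session")
def small_cohort():
    """Two-ancestry HWE cohort of 1,000 samples over 30 variants."""
    rng = np.random.default_rng(5)
    vids = [f"rs{j}" for j in range(30)]
    spec = CohortSpec(
        n_samples={"EUR": 500, "AFR": 500},
        maf_by_ancestry={"EUR": rng.uniform(0.05, 0.5, 30), "AFR": rng.uniform(0.05, 0.5, 30)},
        n_pcs=3,
        seed=9,
    )
    dosages, covariates = simulate_cohort(spec, vids)
    return dosages, covariates


@pytest.fixture()
def assoc_tsv(tmp_path):
    """Write a tiny well-formed association table, return its path."""
    df = pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "effect_allele": ["A", "G", "C", "T", "A"],
            "other_allele": ["G", "A", "T", "C", "C"],
            "trait": ["urate"] * 3 + ["BMI"] * 2,
            "beta": [0.1, -0.2, 0.05, 0.3, -0.1],
            "se": [0.05, 0.04, 0.02, 0.1, 0.05],
            "p_value": [1e-8, 1e-9, 1e-7, 1e-10, 1e-8],
            "n": [10000, 20000, 15000, 50000, 30000],
            "gender_specific": [False] * 5,
            "study": [f"GCST{i}" for i in range(5)],
        }
    )
    path = tmp_path / "assoc.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path
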