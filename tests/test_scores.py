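"""Polygenic scoring: arithmetic, standardization, distribution tests, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nephroclust import (
    ClusterScorer,
    CohortSpec,
    compute_cpgs,
    decile_overlap,
    simulate_cohort,
    standardize_scores,
)
from nephroclust.scores import test_distributions as distribution_tests
from nephroclust.scores import CpgsTable, anderson_darling_normal, count_modes


def _weights(values, vids=None):
    vids = vids or [f"rs{j}" for j in range(len(values))]
    return pd.DataFrame([values], index=["c0"], columns=vids)


class TestComputeCpgs:
    def test_weighted_sum_arithmetic(self):
        W = _weights([4.6, 0.2])
        d = pd.DataFrame([[2.0, 1.0]], index=["s1"], columns=["rs0", "rs1"])
        assert compute_cpgs(W, d).raw.loc["s1", "c0"] == pytest.approx(9.4)

    def test_zero_dosages_zero_score(self):
        W = _weights([1.0, 2.0, 3.0])
        d = pd.DataFrame(np.zeros((4, 3)), columns=W.columns)
        assert (compute_cpgs(W, d).raw == 0).all().all()

    def test_matches_bruteforce_oracle(self, small_cohort):
        dosages, _ = small_cohort
        rng = np.random.default_rng(2)
        W = pd.DataFrame(
            rng.uniform(0, 1, (3, dosages.shape[1])),
            index=["c0", "c1", "c2"],
            columns=dosages.columns,
        )
        raw = compute_cpgs(W, dosages).raw
        # independent loop-and-sum oracle
        for sid in dosages.index[::97]:
            for k in W.index:
                expected = sum(
                    W.loc[k, v] * dosages.loc[sid, v] for v in dosages.columns
                )
                assert raw.loc[sid, k] == pytest.approx(expected, abs=1e-10)

    def test_linearity_in_weights(self, small_cohort):
        dosages, _ = small_cohort
        rng = np.random.default_rng(3)
        W = pd.DataFrame(
            rng.uniform(0, 1, (2, dosages.shape[1])), index=["a", "b"], columns=dosages.columns
        )
        r1 = compute_cpgs(W, dosages).raw
        r2 = compute_cpgs(2.5 * W, dosages).raw
        assert np.allclose(2.5 * r1.to_numpy(), r2.to_numpy(), atol=1e-10)

    def test_missing_variants_imputed_or_error(self, small_cohort):
        dosages, _ = small_cohort
        vids = list(dosages.columns) + ["rs_missing"]
        W = pd.DataFrame(np.ones((1, len(vids))), index=["c0"], columns=vids)
        table = compute_cpgs(W, dosages, min_coverage=0.9)  # 30/31 present
        assert table.raw.notna().all().all()
        many_missing = [f"novel{j}" for j in range(60)] + list(dosages.columns)
        W2 = pd.DataFrame(np.ones((1, len(many_missing))), index=["c0"], columns=many_missing)
        with pytest.raises(ValueError, match="floor"):
            compute_cpgs(W2, dosages, min_coverage=0.9)


class TestStandardize:
    def test_self_reference_zero_mean_unit_sd(self, small_cohort):
        dosages, _ = small_cohort
        W = _weights(list(np.linspace(0.1, 1, 30)), vids=list(dosages.columns))
        table = standardize_scores(compute_cpgs(W, dosages))
        assert abs(table.z.mean()).max() < 1e-8
        assert np.allclose(table.z.std(ddof=0), 1.0, atol=1e-8)

    def test_group_with_higher_maf_shifts_up(self):
        spec = CohortSpec(
            n_samples={"A": 2000, "B": 2000},
            maf_by_ancestry={"A": np.array([0.05]), "B": np.array([0.40])},
            n_pcs=0,
            seed=4,
        )
        dosages, cov = simulate_cohort(spec, ["rs0"])
        table = standardize_scores(compute_cpgs(_weights([1.0], ["rs0"]), dosages))
        za = table.z.loc[cov["ancestry"] == "A", "c0"].mean()
        zb = table.z.loc[cov["ancestry"] == "B", "c0"].mean()
        assert zb > za

    def test_constant_scores_error(self):
        raw = pd.DataFrame({"c0": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="SD"):
            standardize_scores(CpgsTable(raw=raw))

    def test_top_decile_flags_include_threshold_ties(self):
        raw = pd.DataFrame({"c0": [1.0] * 9 + [5.0] * 3})  # ties above Q90
        table = standardize_scores(CpgsTable(raw=raw))
        assert table.top_decile["c0"].sum() == 3


class TestScorerEstimator:
    def test_transform_matches_function_path(self, small_cohort):
        dosages, _ = small_cohort
        rng = np.random.default_rng(8)
        W = pd.DataFrame(
            rng.uniform(0, 1, (2, dosages.shape[1])), index=["a", "b"], columns=dosages.columns
        )
        scorer = ClusterScorer(weights=W).fit(dosages)
        z1 = scorer.transform(dosages)
        z2 = standardize_scores(compute_cpgs(W, dosages)).z
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_subcohort_scored_against_full_reference(self, small_cohort):
        dosages, cov = small_cohort
        W = _weights(list(np.linspace(0.1, 1, 30)), vids=list(dosages.columns))
        scorer = ClusterScorer(weights=W).fit(dosages)
        sub = dosages.loc[cov["ancestry"] == "EUR"]
        z_sub = scorer.transform(sub)
        # group means need not be zero on the common reference scale
        assert abs(z_sub.mean()).max() > 0 or len(z_sub) == len(dosages)


class TestAndersonDarling:
    @pytest.mark.filterwarnings("ignore::FutureWarning")
    def test_statistic_matches_scipy(self):
        x = np.random.default_rng(0).normal(size=500)
        a2s, _ = anderson_darling_normal(x)
        expected = stats.anderson(x, dist="norm").statistic * (1 + 0.75 / 500 + 2.25 / 500**2)
        assert a2s == pytest.approx(expected, rel=1e-8)

    def test_null_calibration(self):
        """On standard-normal draws the test rejects at ~5%."""
        hits = 0
        reps = 40
        for seed in range(reps):
            x = np.random.default_rng(seed).normal(size=5000)
            _, p = anderson_darling_normal(x)
            hits += p > 0.05
        assert hits >= 33  # ~95% of replicates keep p > 0.05

    def test_rejects_bimodal(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-2, 0.5, 2500), rng.normal(2, 0.5, 2500)])
        _, p = anderson_darling_normal(x)
        assert p < 1e-6


class TestModesAndDistributions:
    def test_trimodal_from_dominant_weight(self):
        """One dominant weight at a MAF-0.3 variant creates three score peaks
        ordered by 0/1/2 copies of the top variant."""
        spec = CohortSpec(
            n_samples={"ALL": 10_000}, maf_by_ancestry={"ALL": np.full(30, 0.3)}, n_pcs=0, seed=3
        )
        dosages, _ = simulate_cohort(spec, [f"rs{j}" for j in range(30)])
        w = np.full(30, 0.1)
        w[0], w[1] = 4.6, 0.2
        table = standardize_scores(compute_cpgs(_weights(list(w)), dosages))
        z = table.z["c0"]
        assert count_modes(z.to_numpy()) == 3
        means = [z[dosages["rs0"] == c].mean() for c in (0, 1, 2)]
        assert means[0] < means[1] < means[2]

    def test_uniform_weights_unimodal(self):
        spec = CohortSpec(
            n_samples={"ALL": 10_000},
            maf_by_ancestry={"ALL": np.random.default_rng(4).uniform(0.05, 0.5, 30)},
            n_pcs=0,
            seed=4,
        )
        dosages, _ = simulate_cohort(spec, [f"rs{j}" for j in range(30)])
        table = standardize_scores(compute_cpgs(_weights([0.3] * 30), dosages))
        assert count_modes(table.z["c0"].to_numpy()) == 1

    def test_polygenic_scale_scores_look_normal(self):
        """With spread weights over 200 variants the score passes the
        Anderson-Darling normality test in most seeds (30-variant scores are
        lattice-valued and detectably discrete at this sample size)."""
        nvar, hits = 200, 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            spec = CohortSpec(
                n_samples={"ALL": 5_000},
                maf_by_ancestry={"ALL": r.uniform(0.05, 0.5, nvar)},
                n_pcs=0,
                seed=seed,
            )
            dosages, _ = simulate_cohort(spec, [f"rs{j}" for j in range(nvar)])
            W = _weights(list(r.uniform(0.1, 0.5, nvar)), vids=list(dosages.columns))
            table = standardize_scores(compute_cpgs(W, dosages))
            _, p = anderson_darling_normal(table.z["c0"].to_numpy())
            hits += p > 0.01
        assert hits >= 3

    def test_identical_groups_mann_whitney_p_near_one(self):
        rng = np.random.default_rng(6)
        raw = pd.DataFrame({"c0": np.tile(rng.normal(size=200), 2)})
        raw.index = [f"s{i}" for i in range(400)]
        labels = pd.Series(["A"] * 200 + ["B"] * 200, index=raw.index)
        table = standardize_scores(CpgsTable(raw=raw))
        rep = distribution_tests(table, labels)
        assert rep.ancestry_pairs["p"].iloc[0] > 0.99

    def test_small_group_not_evaluable(self):
        rng = np.random.default_rng(7)
        raw = pd.DataFrame({"c0": rng.normal(size=30)}, index=[f"s{i}" for i in range(30)])
        labels = pd.Series(["A"] * 25 + ["B"] * 5, index=raw.index)
        rep = distribution_tests(standardize_scores(CpgsTable(raw=raw)), labels)
        b_row = rep.normality[rep.normality["cohort"] == "B"].iloc[0]
        assert not b_row["evaluable"]
        assert not rep.ancestry_pairs["evaluable"].iloc[0]


class TestDecileOverlap:
    def test_independent_clusters_closed_form(self):
        """For 9 independent continuous scores, P(>=1 top decile) = 1 - 0.9^9."""
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.normal(size=(40_000, 9)), columns=[f"c{k}" for k in range(9)])
        ov = decile_overlap(standardize_scores(CpgsTable(raw=raw)))
        assert ov["frac_ge1"] == pytest.approx(1 - 0.9**9, abs=0.01)

    def test_single_cluster_exactly_ten_percent(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame({"c0": rng.normal(size=10_000)})
        ov = decile_overlap(standardize_scores(CpgsTable(raw=raw)))
        assert ov["frac_ge1"] == pytest.approx(0.10, abs=0.005)

    def test_perfectly_correlated_clusters(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=5_000)
        raw = pd.DataFrame({f"c{k}": s for k in range(4)})
        ov = decile_overlap(standardize_scores(CpgsTable(raw=raw)))
        assert ov["frac_ge1"] == pytest.approx(0.10, abs=0.005)
        assert ov["frac_ge4_of_risk"] == pytest.approx(1.0)

    def test_shared_variants_between_bounds(self, small_cohort):
        """Clusters sharing variants overlap more than independence predicts."""
        dosages, _ = small_cohort
        rng = np.random.default_rng(3)
        K = 4
        W = pd.DataFrame(
            rng.uniform(0, 1, (K, dosages.shape[1])),
            index=[f"c{k}" for k in range(K)],
            columns=dosages.columns,
        )
        ov = decile_overlap(standardize_scores(compute_cpgs(W, dosages)))
        assert 0.10 < ov["frac_ge1"] < 1 - 0.9**K
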