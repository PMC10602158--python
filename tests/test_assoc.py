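"""Ingest, LD expansion, allele alignment, filters and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephroclust import (
    AssociationRecord,
    FactorPlant,
    FilterParams,
    align_effect_alleles,
    apply_filters,
    build_matrix,
    expand_ld_proxies,
    parse_catalog_associations,
    simulate_catalog_table,
    standardize_effect,
)
from nephroclust.assoc import EffectMatrix, records_to_frame, sweep_min_variants


def _rec(**kw):
    base = dict(
        variant_id="rs1",
        effect_allele="A",
        other_allele="G",
        trait_name="urate",
        B=0.1,
        SE=0.05,
        p_value=1e-8,
        study_n=10_000,
    )
    base.update(kw)
    return AssociationRecord(**base)


class TestParse:
    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "variant_id\teffect_allele\tother_allele\ttrait\tbeta\tse\tp_value\tn\tgender_specific\tstudy\n"
        )
        records, rejects = parse_catalog_associations(path)
        assert records == [] and len(rejects) == 0

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant_id\ttrait\n rs1\turate\n")
        with pytest.raises(ValueError, match="p_value|beta|se|effect_allele"):
            parse_catalog_associations(path)

    def test_nonpositive_se_goes_to_rejects(self, tmp_path, assoc_tsv):
        df = pd.read_csv(assoc_tsv, sep="\t")
        df.loc[0, "se"] = 0.0
        path = tmp_path / "se0.tsv"
        df.to_csv(path, sep="\t", index=False)
        records, rejects = parse_catalog_associations(path)
        assert len(records) == 4
        assert rejects["reason"].tolist() == ["nonpositive SE"]

    def test_round_trip(self, tmp_path, assoc_tsv):
        records, _ = parse_catalog_associations(assoc_tsv)
        assert len(records) == 5
        path = tmp_path / "rt.tsv"
        records_to_frame(records).to_csv(path, sep="\t", index=False)
        again, _ = parse_catalog_associations(path)
        assert again == records


class TestLdProxies:
    @pytest.fixture()
    def ld(self):
        return pd.DataFrame(
            {
                "lead": ["rsA", "rsA", "rsB", "rsB"],
                "proxy": ["rsP1", "rsP2", "rsP2", "rsP3"],
                "r2": [0.59, 0.7, 0.9, 1.0],
            }
        )

    def test_threshold_is_inclusive_at_r2_min(self, ld):
        out = expand_ld_proxies(["rsA", "rsB"], ld, r2_min=0.6)
        assert "rsP1" not in out["rsA"]  # r2=0.59 just below threshold
        assert "rsP3" in out["rsB"]

    def test_lead_always_its_own_proxy(self, ld):
        out = expand_ld_proxies(["rsA"], ld, r2_min=1.0)
        assert out["rsA"] == ["rsA"]

    def test_shared_proxy_claimed_by_max_r2(self, ld):
        out = expand_ld_proxies(["rsA", "rsB"], ld, r2_min=0.6)
        assert "rsP2" in out["rsB"] and "rsP2" not in out["rsA"]

    def test_tie_goes_to_first_lead(self):
        ld = pd.DataFrame(
            {"lead": ["rsB", "rsA"], "proxy": ["rsP", "rsP"], "r2": [0.8, 0.8]}
        )
        out = expand_ld_proxies(["rsA", "rsB"], ld)
        assert "rsP" in out["rsA"]

    def test_absent_lead_maps_to_itself(self, ld):
        out = expand_ld_proxies(["rsZ"], ld)
        assert out["rsZ"] == ["rsZ"]

    def test_invalid_r2_rejected(self):
        ld = pd.DataFrame({"lead": ["a"], "proxy": ["b"], "r2": [1.2]})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            expand_ld_proxies(["a"], ld)


class TestAlignAlleles:
    RISK = pd.DataFrame({"variant_id": ["rs1"], "risk_allele": ["A"]})

    def test_identity_when_effect_is_risk(self):
        aligned, rejects = align_effect_alleles([_rec()], self.RISK)
        assert aligned[0].B == 0.1 and len(rejects) == 0

    def test_sign_flip_when_other_is_risk(self):
        rec = _rec(effect_allele="G", other_allele="A", B=0.2)
        aligned, _ = align_effect_alleles([rec], self.RISK)
        assert aligned[0].B == -0.2
        assert aligned[0].effect_allele == "A"

    def test_strand_complement_resolved(self):
        # T/C is the reverse strand of A/G: unambiguous, B unchanged
        rec = _rec(effect_allele="T", other_allele="C")
        aligned, rejects = align_effect_alleles([rec], self.RISK)
        assert len(aligned) == 1 and aligned[0].effect_allele == "A"
        assert aligned[0].B == 0.1

    @pytest.mark.parametrize("ea,oa", [("T", "A"), ("C", "G"), ("G", "C")])
    def test_ambiguous_mismatch_rejected(self, ea, oa):
        rec = _rec(effect_allele=ea, other_allele=oa)
        aligned, rejects = align_effect_alleles([rec], self.RISK)
        if "A" in (ea, oa):  # direct match still allowed for A/T
            assert len(aligned) == 1
        else:
            assert len(aligned) == 0
            assert "ambiguous" in rejects["reason"].iloc[0]

    def test_missing_variant_rejected_with_reason(self):
        rec = _rec(variant_id="rs999")
        aligned, rejects = align_effect_alleles([rec], self.RISK)
        assert len(aligned) == 0
        assert "missing" in rejects["reason"].iloc[0]


class TestFilters:
    def test_weak_p_boundary(self):
        kept, rep = apply_filters([_rec(p_value=2e-6), _rec(p_value=1e-6), _rec(p_value=9.9e-7)])
        assert rep.removed["weak_p"] == 2  # threshold is strictly less-than
        assert len(kept) == 0  # survivor then dropped as rare trait
        assert rep.removed["rare_trait"] == 1

    def test_named_kidney_trait_removed(self):
        recs = [_rec(trait_name="Estimated Glomerular Filtration Rate")]
        _, rep = apply_filters(recs)
        assert rep.removed["ckd_trait"] == 1

    def test_small_n_boundary(self):
        _, rep = apply_filters([_rec(study_n=99), _rec(study_n=100)])
        assert rep.removed["small_n"] == 1

    @pytest.mark.parametrize("n_variants,kept_expected", [(5, 5), (4, 0)])
    def test_min_variants_boundary(self, n_variants, kept_expected):
        recs = [_rec(variant_id=f"rs{i}") for i in range(n_variants)]
        kept, _ = apply_filters(recs)
        assert len(kept) == kept_expected

    def test_counts_conserved_and_idempotent(self):
        plant = FactorPlant(k_true=2, n_traits=12, n_variants=24, seed=6)
        table, _ = simulate_catalog_table(
            plant, {"small_n": 2, "weak_p": 3, "gender_specific": 1, "ckd_trait": 2, "rare_trait": 2}
        )
        records = [
            _rec(
                variant_id=r.variant_id, trait_name=r.trait, B=r.beta, SE=r.se,
                p_value=r.p_value, study_n=r.n, gender_specific=r.gender_specific,
            )
            for r in table.itertuples(index=False)
        ]
        kept, rep = apply_filters(records)
        assert sum(rep.removed.values()) + len(kept) == len(records)
        kept2, rep2 = apply_filters(kept)
        assert kept2 == kept and sum(rep2.removed.values()) == 0

    def test_report_matches_planted_violation_counts(self):
        planted = {"small_n": 3, "weak_p": 2, "gender_specific": 2, "ckd_trait": 1, "rare_trait": 2}
        plant = FactorPlant(k_true=2, n_traits=12, n_variants=24, seed=8)
        table, truth = simulate_catalog_table(plant, planted)
        path_records = [
            _rec(
                variant_id=r.variant_id, trait_name=r.trait, B=r.beta, SE=r.se,
                p_value=r.p_value, study_n=r.n, gender_specific=r.gender_specific,
            )
            for r in table.itertuples(index=False)
        ]
        _, rep = apply_filters(path_records)
        assert rep.removed == truth["violation_counts"]

    def test_sweep_counts_monotone(self):
        recs = [
            _rec(trait_name=f"t{t}", variant_id=f"rs{v}")
            for t in range(4)
            for v in range(2 + 2 * t)
        ]
        sweep = sweep_min_variants(recs, thresholds=range(2, 9))
        assert (np.diff(sweep["retained_associations"]) <= 0).all()


class TestStandardize:
    @pytest.mark.parametrize(
        "b,se,expected", [(0.10, 0.05, 2.0), (0.0, 0.1, 0.0), (-0.30, 0.10, -3.0)]
    )
    def test_beta_is_b_over_se(self, b, se, expected):
        assert standardize_effect(_rec(B=b, SE=se)) == pytest.approx(expected)

    def test_nonpositive_se_error(self):
        rec = _rec()
        rec.SE = 0.0
        with pytest.raises(ValueError):
            standardize_effect(rec)


class TestBuildMatrix:
    def test_split_mode_construction(self):
        recs = [
            _rec(variant_id="rs1", B=0.10, SE=0.05),   # beta = +2
            _rec(variant_id="rs2", B=-0.30, SE=0.10),  # beta = -3
        ]
        m = build_matrix(recs, sign_mode="split")
        df = m.to_frame()
        assert list(df.index) == ["urate|+", "urate|-"]
        assert df.loc["urate|+"].tolist() == pytest.approx([2.0, 0.0])
        assert df.loc["urate|-"].tolist() == pytest.approx([0.0, 3.0])

    def test_split_equals_clip_when_all_positive(self):
        recs = [_rec(variant_id=f"rs{i}", B=0.1 * (i + 1)) for i in range(4)]
        split = build_matrix(recs, sign_mode="split").to_frame()
        clip = build_matrix(recs, sign_mode="clip").to_frame()
        assert np.allclose(split.to_numpy(), clip.to_numpy())

    def test_duplicate_pair_keeps_smaller_p(self):
        recs = [
            _rec(B=0.1, p_value=1e-8),
            _rec(B=0.5, p_value=1e-12),
            _rec(variant_id="rs2", B=0.2),
        ]
        m = build_matrix(recs)
        assert m.to_frame().loc["urate|+", "rs1"] == pytest.approx(10.0)  # 0.5/0.05

    def test_tsv_round_trip(self, tmp_path):
        recs = [_rec(variant_id="rs1", B=0.1), _rec(variant_id="rs2", B=-0.2)]
        m = build_matrix(recs)
        path = tmp_path / "x.tsv"
        m.to_tsv(path)
        back = EffectMatrix.from_tsv(path)
        assert np.allclose(back.values, m.values)
        assert back.sign_registry == m.sign_registry
        assert back.n_traits == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        betas=st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=12
        )
    )
    def test_split_reconstruction_property(self, betas):
        """(+row) - (-row) per trait reproduces the signed beta vector."""
        recs = [
            _rec(variant_id=f"rs{i:02d}", B=b * 0.05, SE=0.05) for i, b in enumerate(betas)
        ]
        m = build_matrix(recs, sign_mode="split")
        df = m.to_frame()
        if len(df):
            pos = df.loc["urate|+"] if "urate|+" in df.index else pd.Series(0.0, index=df.columns)
            neg = df.loc["urate|-"] if "urate|-" in df.index else pd.Series(0.0, index=df.columns)
            recon = pos - neg
        else:
            recon = pd.Series(dtype=float)
        for i, b in enumerate(betas):
            assert recon.get(f"rs{i:02d}", 0.0) == pytest.approx(b, abs=1e-9)
        assert (df.to_numpy() >= 0).all()
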