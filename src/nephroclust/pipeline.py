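"""End-to-end orchestration: matrix -> rank selection -> factorization ->
scores -> PheWAS -> report, under one config and one global seed.

The global seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` derivation, so any stage can be rerun in
isolation and reproduce its part of a pipeline run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, nmf, phewas as phewas_mod, scores as scores_mod, synthetic

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "build_matrix", "select_rank", "factorize", "score", "phewas")


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults are the published values."""

    # stage toggles
    simulate: bool = True
    run_rank_selection: bool = True
    run_bnmf: bool = False
    run_phewas: bool = True
    # matrix assembly
    r2_min: float = 0.6
    p_max: float = 1e-6
    n_min: int = 100
    min_variants_per_trait: int = 5
    sign_mode: str = "split"
    # factorization
    k: int | None = None
    k_min: int = 2
    k_max: int = 20
    n_init: int = 30
    max_iter: int = 10_000
    conv_window: int = 80
    bnmf_runs: int = 1_000
    bnmf_max_iter: int = 200_000
    # PheWAS
    min_participants: int = 100
    family_alpha: float = 0.05
    # synthetic cohort
    sim_k_true: int = 3
    sim_n_traits: int = 30
    sim_n_variants: int = 60
    sim_noise_sd: float = 0.05
    sim_n_samples: int = 2_000
    # paths & seed
    assoc_path: str | None = None
    ld_path: str | None = None
    risk_allele_path: str | None = None
    genotype_path: str | None = None
    covariate_path: str | None = None
    phenotype_path: str | None = None
    out_dir: str = "nephroclust_run"
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            stage: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for stage, child in zip(_STAGES, children)
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages, writing every artifact plus a manifest.

    Returns the manifest (stage seeds, artifact hashes, key results). A
    stage failure raises with the stage name; completed artifacts remain on
    disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {"config": asdict(config), "stage_seeds": seeds, "artifacts": {}, "results": {}}

    def _save(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "simulate"
    try:
        if config.simulate:
            plant = synthetic.FactorPlant(
                k_true=config.sim_k_true,
                n_traits=config.sim_n_traits,
                n_variants=config.sim_n_variants,
                noise_sd=config.sim_noise_sd,
                seed=seeds["simulate"],
            )
            catalog, truth = synthetic.simulate_catalog_table(
                plant, {"small_n": 2, "weak_p": 2, "ckd_trait": 1, "gender_specific": 1}
            )
            assoc_path = out / "associations.tsv"
            catalog.to_csv(assoc_path, sep="\t", index=False)
            _save("associations", assoc_path)
            risk = pd.DataFrame(
                {
                    "variant_id": sorted(catalog["variant_id"].unique()),
                }
            )
            first_alleles = catalog.drop_duplicates("variant_id").set_index("variant_id")
            risk["risk_allele"] = [first_alleles.loc[v, "effect_allele"] for v in risk["variant_id"]]
            risk_path = out / "risk_alleles.tsv"
            risk.to_csv(risk_path, sep="\t", index=False)
            _save("risk_alleles", risk_path)
            variant_ids = truth["variant_ids"]
            rng = np.random.default_rng(seeds["simulate"] + 1)
            spec = synthetic.CohortSpec(
                n_samples={"EUR": config.sim_n_samples // 2, "AFR": config.sim_n_samples - config.sim_n_samples // 2},
                maf_by_ancestry={
                    "EUR": rng.uniform(0.05, 0.5, len(variant_ids)),
                    "AFR": rng.uniform(0.05, 0.5, len(variant_ids)),
                },
                seed=seeds["simulate"] + 2,
            )
            dosages, covariates = synthetic.simulate_cohort(spec, variant_ids)
            geno_path, cov_path = out / "dosages.tsv", out / "covariates.tsv"
            dosages.to_csv(geno_path, sep="\t", index_label="sample_id")
            covariates.to_csv(cov_path, sep="\t", index_label="sample_id")
            _save("dosages", geno_path)
            _save("covariates", cov_path)
            manifest["results"]["simulated_k_true"] = plant.k_true
        else:
            assoc_path = Path(config.assoc_path)
            risk_path = Path(config.risk_allele_path) if config.risk_allele_path else None
            dosages = (
                pd.read_csv(config.genotype_path, sep="\t", index_col="sample_id")
                if config.genotype_path
                else None
            )
            covariates = (
                pd.read_csv(config.covariate_path, sep="\t", index_col="sample_id")
                if config.covariate_path
                else None
            )

        stage = "build_matrix"
        records, rejects = assoc.parse_catalog_associations(assoc_path)
        if config.ld_path:
            ld = pd.read_csv(config.ld_path, sep="\t")
            leads = sorted({r.variant_id for r in records})
            proxy_map = assoc.expand_ld_proxies(leads, ld, config.r2_min)
            back = assoc.proxies_to_leads(proxy_map)
            for r in records:
                r.variant_id = back.get(r.variant_id, r.variant_id)
        if risk_path is not None:
            risk_table = pd.read_csv(risk_path, sep="\t")
            records, align_rejects = assoc.align_effect_alleles(records, risk_table)
        retained, filt_report = assoc.apply_filters(
            records,
            assoc.FilterParams(
                p_max=config.p_max,
                n_min=config.n_min,
                min_variants_per_trait=config.min_variants_per_trait,
            ),
        )
        matrix = assoc.build_matrix(retained, sign_mode=config.sign_mode)
        mat_path = out / "effect_matrix.tsv"
        matrix.to_tsv(mat_path)
        _save("effect_matrix", mat_path)
        (out / "filter_report.json").write_text(filt_report.to_json())
        _save("filter_report", out / "filter_report.json")
        manifest["results"]["filter_report"] = json.loads(filt_report.to_json())

        stage = "select_rank"
        x = matrix.to_frame()
        if config.run_rank_selection and config.k is None:
            k_hi = min(config.k_max, min(x.shape) - 1)
            chosen_k, rank_report, trace = nmf.select_rank(
                x,
                k_range=range(config.k_min, k_hi + 1),
                restarts=5,
                seed=seeds["select_rank"],
                max_iter=min(config.max_iter, 2_000),
            )
            rank_report.to_csv(out / "rank_selection.tsv", sep="\t", index=False)
            _save("rank_selection", out / "rank_selection.tsv")
            manifest["results"]["chosen_k"] = chosen_k
        else:
            chosen_k = config.k or config.sim_k_true
            manifest["results"]["chosen_k"] = chosen_k
        if config.run_bnmf:
            k_mode, runs = nmf.bnmf_ard(
                x,
                K_max=min(config.k_max, min(x.shape)),
                runs=config.bnmf_runs,
                max_iter=config.bnmf_max_iter,
                seed=seeds["select_rank"] + 1,
            )
            runs.to_csv(out / "bnmf_runs.tsv", sep="\t", index=False)
            _save("bnmf_runs", out / "bnmf_runs.tsv")
            manifest["results"]["bnmf_k_mode"] = k_mode

        stage = "factorize"
        result = nmf.factorize(
            x,
            chosen_k,
            n_init=config.n_init,
            max_iter=config.max_iter,
            conv_window=config.conv_window,
            seed=seeds["factorize"],
        )
        h_df = pd.DataFrame(result.H, index=matrix.row_labels, columns=[f"cluster_{i}" for i in range(chosen_k)])
        w_df = pd.DataFrame(result.W, index=[f"cluster_{i}" for i in range(chosen_k)], columns=matrix.variant_ids)
        h_df.to_csv(out / "H.tsv", sep="\t", index_label="component")
        w_df.to_csv(out / "W.tsv", sep="\t", index_label="cluster")
        _save("H", out / "H.tsv")
        _save("W", out / "W.tsv")
        summary = nmf.summarize_clusters(result, matrix.sign_registry)
        (out / "cluster_summary.json").write_text(
            json.dumps(summary.clusters, indent=2, default=float)
        )
        summary.to_frame().to_csv(out / "top_traits.tsv", sep="\t", index=False)
        _save("cluster_summary", out / "cluster_summary.json")
        manifest["results"]["frobenius_error"] = result.frobenius_error

        stage = "score"
        cpgs_table = None
        if dosages is not None:
            table = scores_mod.compute_cpgs(w_df, dosages)
            cpgs_table = scores_mod.standardize_scores(table)
            cpgs_table.to_tsv(out / "cpgs.tsv")
            _save("cpgs", out / "cpgs.tsv")
            ancestry = covariates["ancestry"] if covariates is not None and "ancestry" in covariates else None
            dist = scores_mod.test_distributions(cpgs_table, ancestry)
            (out / "distributions.json").write_text(dist.to_json())
            _save("distributions", out / "distributions.json")
            manifest["results"]["decile_overlap"] = scores_mod.decile_overlap(cpgs_table)

        stage = "phewas"
        if config.run_phewas and cpgs_table is not None:
            if config.simulate:
                # phenotypes named after each cluster's top traits, driven by
                # that cluster's score in the trait's direction, so the
                # replication report closes the loop on the planted truth
                plants, seen = [], set()
                for c in summary.clusters:
                    for t in c["top_traits"][:5]:
                        if t["trait"] in seen:
                            continue
                        seen.add(t["trait"])
                        eff = 0.3 if t["direction"] == "+" else -0.3
                        plants.append(
                            synthetic.PhenotypePlant(
                                name=t["trait"], kind="quantitative",
                                target_cluster=c["cluster"], effect_size=eff,
                                covariate_effects={"age": 0.01},
                            )
                        )
                plants += [
                    synthetic.PhenotypePlant(name=f"null_{i}", kind="quantitative")
                    for i in range(3)
                ]
                pheno, dx, code_map = synthetic.simulate_phenotypes(
                    cpgs_table.z, plants, covariates, seed=seeds["phewas"]
                )
                pheno.to_csv(out / "phenotypes.tsv", sep="\t", index_label="sample_id")
                _save("phenotypes", out / "phenotypes.tsv")
            else:
                pheno = pd.read_csv(config.phenotype_path, sep="\t", index_col="sample_id")
            cov_cols = [c for c in ("age", "sex") if covariates is not None and c in covariates]
            cov_cols += [c for c in covariates.columns if c.startswith("PC")][:10] if covariates is not None else []
            pw = phewas_mod.run_phewas(
                cpgs_table.z,
                pheno,
                covariates[cov_cols] if covariates is not None else None,
                min_n=config.min_participants,
                family_alpha=config.family_alpha,
            )
            pw.to_csv(out / "phewas.tsv", sep="\t", index=False)
            _save("phewas", out / "phewas.tsv")
            rep = phewas_mod.replication_report(pw.assign(trait=pw["trait"]), summary)
            (out / "replication.json").write_text(rep.to_json())
            _save("replication", out / "replication.json")
            manifest["results"]["n_phewas_rows"] = len(pw)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True))
    return manifest


def report(out_dir, make_plots: bool = True) -> Path:
    """Render a run's artifacts into summary tables (and plots if possible).

    Missing artifacts skip their section with a notice; regeneration is
    idempotent.
    """
    out = Path(out_dir)
    lines = ["# Run summary", ""]
    summary_path = out / "cluster_summary.json"
    if summary_path.exists():
        clusters = json.loads(summary_path.read_text())
        lines.append("## Clusters (SNP count, Q90 weight)")
        lines.append("cluster\tsnps\tq90_weight")
        for c in clusters:
            lines.append(f"{c['cluster']}\t{c['n_variants_nonzero']}\t{c['q90_weight']:.4g}")
        lines.append("")
        lines.append("## Top traits per cluster")
        for c in clusters:
            tops = ", ".join(
                f"{t['trait']}({t['direction']}, {t['loading']:.3g})" for t in c["top_traits"][:7]
            )
            lines.append(f"cluster {c['cluster']}: {tops}")
        lines.append("")
    else:
        lines.append("[cluster summary missing; section skipped]")
    rep_path = out / "replication.json"
    if rep_path.exists():
        rep = json.loads(rep_path.read_text())
        lines.append("## Replication")
        for k, v in rep.items():
            lines.append(f"cluster {k}: {v['replicated_count']} of top traits replicated")
    cpgs_path = out / "cpgs.tsv"
    if make_plots and cpgs_path.exists():
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            table = pd.read_csv(cpgs_path, sep="\t", index_col="sample_id")
            zcols = [c for c in table.columns if c.startswith("z_")]
            fig, axes = plt.subplots(1, max(len(zcols), 1), figsize=(3 * max(len(zcols), 1), 3))
            axes = np.atleast_1d(axes)
            for ax, c in zip(axes, zcols):
                ax.hist(table[c], bins=60, density=True)
                ax.set_title(c)
                ax.set_xlabel("z")
            fig.tight_layout()
            fig.savefig(out / "cpgs_distributions.png", dpi=100)
            plt.close(fig)
            lines.append("\n[cPGS distribution plots written to cpgs_distributions.png]")
        except Exception as exc:  # plotting is best-effort
            lines.append(f"\n[plots skipped: {exc}]")
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
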