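"""cPGS phenome-wide association study.

Each cluster's standardized polygenic score is regressed against every
eligible phenotype: ordinary least squares for quantitative traits (with the
outcome and continuous predictors z-scored, so the coefficient is a
standardized estimate) and logistic regression for binary phecode-derived
traits (odds ratio per SD of cPGS, Wald 95% CI), adjusting for sex, age and
genetic principal components. A phecode case requires at least two mapped
diagnostic codes; traits are eligible only when present or measured in at
least 100 participants. Bonferroni control uses the post-filter trait count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def bonferroni_alpha(n_quant: int, n_binary: int, family_alpha: float = 0.05) -> float:
    """Family-wise alpha threshold: family_alpha / (n_quant + n_binary)."""
    total = n_quant + n_binary
    if total <= 0:
        raise ValueError("at least one test is required")
    return family_alpha / total


def map_phecodes(
    dx_codes: pd.DataFrame,
    code_map: pd.DataFrame,
    min_codes: int = 2,
    exclude_single: bool = False,
    samples=None,
) -> tuple[pd.DataFrame, int]:
    """Assign case/control/excluded status per sample per phecode.

    A sample is a case for a phecode when it carries at least ``min_codes``
    diagnostic codes mapping to it ("rule of two"); otherwise it is a
    control, unless ``exclude_single`` is set and it carries exactly one
    code, in which case it is excluded from that phecode's analysis.
    Diagnostic codes with no mapping are ignored and tallied. ``samples``
    optionally lists the full cohort, so zero-code samples appear as
    controls. Returns (long table with sample_id, phecode, code_count,
    status; unmapped count).
    """
    mapping = dict(zip(code_map["code"].astype(str), code_map["phecode"].astype(str)))
    unmapped = int((~dx_codes["code"].astype(str).isin(mapping)).sum())
    mapped = dx_codes[dx_codes["code"].astype(str).isin(mapping)].copy()
    mapped["phecode"] = mapped["code"].astype(str).map(mapping)
    counts = (
        mapped.groupby(["sample_id", "phecode"]).size().rename("code_count").reset_index()
    )
    if samples is None:
        samples = sorted(dx_codes["sample_id"].unique())
    samples = pd.Index(samples, name="sample_id")
    phecodes = sorted(set(mapping.values()))
    full = pd.MultiIndex.from_product([samples, phecodes], names=["sample_id", "phecode"])
    table = (
        counts.set_index(["sample_id", "phecode"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    status = np.where(table["code_count"] >= min_codes, "case", "control")
    if exclude_single:
        status = np.where(table["code_count"] == 1, "excluded", status)
    table["status"] = status
    return table, unmapped


@dataclass
class PhewasRow:
    """One trait x cluster regression: standardized effect with 95% CI."""

    cluster: str
    trait: str
    model: str  # "linear" or "logistic"
    n_used: int
    estimate: float  # standardized coefficient (linear) or OR per SD (logistic)
    ci_low: float
    ci_high: float
    p_value: float
    passes_bonferroni: bool = False
    converged: bool = True


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=0)
    return (a - a.mean()) / sd if sd > 0 else a - a.mean()


def _design(z: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones_like(z), z]
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c].to_numpy(dtype=float)
            # z-score continuous covariates; leave binary indicators as-is
            cols.append(v if set(np.unique(v)) <= {0.0, 1.0} else _zscore(v))
    return np.column_stack(cols)


def fit_trait(
    y,
    cpgs_z,
    covariates: pd.DataFrame | None = None,
    model: str = "linear",
    cluster: str = "",
    trait: str = "",
) -> PhewasRow:
    """Fit one phenotype against one cluster's standardized score.

    Linear: OLS on the z-scored outcome and z-scored continuous predictors
    (refit standardization), so the coefficient is in SD-per-SD units.
    Logistic: maximum likelihood; the OR is per SD of cPGS with a Wald 95%
    CI on the log-odds scale. Non-convergence or separation yields a flagged
    row with a not-evaluable p-value, never a silent drop.
    """
    y = np.asarray(y, dtype=float)
    z = _zscore(np.asarray(cpgs_z, dtype=float))
    n = len(y)
    X = _design(z, covariates)
    crit = stats.norm.ppf(0.975)
    if model == "linear":
        ys = _zscore(y)
        beta, _, rank, _ = np.linalg.lstsq(X, ys, rcond=None)
        resid = ys - X @ beta
        dof = n - X.shape[1]
        if dof <= 0 or rank < X.shape[1]:
            return PhewasRow(cluster, trait, model, n, np.nan, np.nan, np.nan, np.nan, converged=False)
        s2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(s2 * xtx_inv[1, 1])
        est = beta[1]
        tval = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), dof)
        ci = stats.t.ppf(0.975, dof) * se
        return PhewasRow(cluster, trait, model, n, float(est), float(est - ci), float(est + ci), float(p))
    elif model == "logistic":
        import statsmodels.api as sm

        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False) or not np.isfinite(fit.bse[1]):
                raise ValueError("logistic fit did not converge")
        except Exception:
            logger.warning("logistic non-convergence for trait %s / cluster %s", trait, cluster)
            return PhewasRow(cluster, trait, model, n, np.nan, np.nan, np.nan, np.nan, converged=False)
        b, se = fit.params[1], fit.bse[1]
        return PhewasRow(
            cluster,
            trait,
            model,
            n,
            float(np.exp(b)),
            float(np.exp(b - crit * se)),
            float(np.exp(b + crit * se)),
            float(2 * stats.norm.sf(abs(b / se))),
        )
    raise ValueError("model must be 'linear' or 'logistic'")


def run_phewas(
    cpgs_z: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_n: int = 100,
    min_cases: int = 20,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every eligible trait x cluster pair and flag Bonferroni passes.

    Phenotype columns with exactly two observed values {0, 1} are treated as
    binary (logistic model; needs >= ``min_cases`` cases and controls),
    everything else as quantitative. Traits observed in fewer than ``min_n``
    participants are dropped before alpha is computed, so the Bonferroni
    denominator is the post-filter trait count. Output is sorted by p within
    cluster.
    """
    idx = cpgs_z.index
    if covariates is not None:
        covariates = covariates.reindex(idx)
    eligible: list[tuple[str, str]] = []
    for trait in phenotypes.columns:
        y = phenotypes[trait].reindex(idx)
        n_obs = int(y.notna().sum())
        if n_obs < min_n:
            continue
        vals = set(y.dropna().unique())
        if vals <= {0, 1}:
            n_case = int((y == 1).sum())
            if n_case < min_cases or (n_obs - n_case) < min_cases:
                continue
            eligible.append((trait, "logistic"))
        else:
            eligible.append((trait, "linear"))
    if not eligible:
        logger.warning("no eligible traits; empty PheWAS result")
        return pd.DataFrame(
            columns=["cluster", "trait", "model", "n_used", "estimate", "ci_low",
                     "ci_high", "p_value", "passes_bonferroni", "converged", "alpha"]
        )
    n_binary = sum(1 for _, m in eligible if m == "logistic")
    alpha = bonferroni_alpha(len(eligible) - n_binary, n_binary, family_alpha)
    rows = []
    for trait, model in eligible:
        y = phenotypes[trait].reindex(idx)
        mask = y.notna().to_numpy()
        cov = covariates.loc[mask] if covariates is not None else None
        if cov is not None:
            cov = cov.dropna(axis=1, how="any")
        for cluster in cpgs_z.columns:
            row = fit_trait(
                y.to_numpy(dtype=float)[mask],
                cpgs_z[cluster].to_numpy()[mask],
                cov,
                model=model,
                cluster=str(cluster),
                trait=trait,
            )
            row.passes_bonferroni = bool(np.isfinite(row.p_value) and row.p_value < alpha)
            rows.append(row.__dict__ | {"alpha": alpha})
    out = pd.DataFrame(rows)
    return out.sort_values(["cluster", "p_value"]).reset_index(drop=True)


@dataclass
class ReplicationReport:
    """Per-cluster tally of top NMF traits confirmed by the PheWAS."""

    per_cluster: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json

        return json.dumps(self.per_cluster, indent=2, default=str)


def replication_report(
    phewas_rows: pd.DataFrame,
    cluster_summary,
    name_map: dict[str, str] | None = None,
    top_n: int = 5,
) -> ReplicationReport:
    """Count which top NMF traits the PheWAS replicates per cluster.

    A top trait replicates when its mapped PheWAS trait passes Bonferroni
    AND the effect direction agrees with the NMF direction (positive
    coefficient / OR > 1 for "+", the reverse for "-"). Unmapped or missing
    traits are listed and count as not replicated.
    """
    name_map = name_map or {}
    report: dict = {}

    def _norm(label) -> str:
        s = str(label)
        return s[len("cluster_"):] if s.startswith("cluster_") else s

    for c in cluster_summary.clusters:
        k = c["cluster"]
        if len(phewas_rows):
            sub = phewas_rows[phewas_rows["cluster"].map(_norm) == _norm(k)]
        else:
            sub = phewas_rows
        entries = []
        n_rep = 0
        for t in c["top_traits"][:top_n]:
            mapped = name_map.get(t["trait"], t["trait"])
            match = sub[sub["trait"] == mapped] if len(sub) else sub
            if len(match) == 0:
                entries.append({"trait": t["trait"], "mapped": mapped, "replicated": False,
                                "reason": "no PheWAS result"})
                continue
            row = match.iloc[0]
            if row["model"] == "logistic":
                positive = row["estimate"] > 1.0
            else:
                positive = row["estimate"] > 0.0
            concordant = positive == (t["direction"] == "+")
            ok = bool(row["passes_bonferroni"]) and concordant
            n_rep += ok
            entries.append(
                {
                    "trait": t["trait"],
                    "mapped": mapped,
                    "replicated": ok,
                    "significant": bool(row["passes_bonferroni"]),
                    "direction_concordant": bool(concordant),
                    "estimate": float(row["estimate"]),
                    "p_value": float(row["p_value"]) if np.isfinite(row["p_value"]) else None,
                }
            )
        report[str(k)] = {"top_traits": entries, "replicated_count": int(n_rep)}
    return ReplicationReport(per_cluster=report)
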