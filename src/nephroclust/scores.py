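"""Cluster-specific polygenic scores (cPGS) and their distributional tests.

A sample's raw score in cluster k is the dosage-weighted sum of that
cluster's variant weights, dosages counted on the kidney-function-decreasing
allele. Scores are standardized (z) within each cluster against a stated
reference cohort — the full cohort by default, so ancestry-group shifts stay
visible when sub-cohorts are compared. Distributional structure (departure
from normality, multimodality driven by a single dominant weight, shifts
between ancestry groups) is tested with Anderson-Darling, KDE peak counting
and Mann-Whitney.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclass
class CpgsTable:
    """Sample x cluster polygenic scores: raw, standardized, top-decile flags."""

    raw: pd.DataFrame
    z: pd.DataFrame | None = None
    top_decile: pd.DataFrame | None = None
    reference: str = "ALL"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def clusters(self) -> list:
        return list(self.raw.columns)

    def to_tsv(self, path) -> None:
        out = self.raw.add_prefix("raw_")
        if self.z is not None:
            out = out.join(self.z.add_prefix("z_"))
        if self.top_decile is not None:
            out = out.join(self.top_decile.astype(int).add_prefix("top_"))
        out.to_csv(path, sep="\t", index_label="sample_id")


class ClusterScorer(BaseEstimator):
    """Transformer from genotype dosages to standardized cluster scores.

    ``fit`` learns per-cluster standardization moments on a reference cohort;
    ``transform`` scores any cohort against that reference, so sub-cohorts
    remain comparable on a common scale.

    Parameters
    ----------
    weights : cluster x variant weight matrix (DataFrame; columns are
        variant ids, index cluster labels).
    min_coverage : minimum fraction of weight variants that must be present
        in the dosage matrix; missing variants are imputed with the sample's
        mean dosage and logged.
    """

    def __init__(self, weights: pd.DataFrame | None = None, min_coverage: float = 0.9):
        self.weights = weights
        self.min_coverage = min_coverage

    def fit(self, X: pd.DataFrame, y=None):
        raw = compute_cpgs(self.weights, X, min_coverage=self.min_coverage).raw
        self.mean_ = raw.mean(axis=0)
        self.std_ = raw.std(axis=0, ddof=0)
        degenerate = self.std_[self.std_ <= 0]
        if len(degenerate):
            raise ValueError(
                f"zero score SD in reference cohort for cluster(s) {list(degenerate.index)}"
            )
        self.decile_threshold_ = raw.quantile(0.9, axis=0, interpolation="linear")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        table = compute_cpgs(self.weights, X, min_coverage=self.min_coverage)
        return (table.raw - self.mean_) / self.std_


def compute_cpgs(
    weights: pd.DataFrame, dosages: pd.DataFrame, min_coverage: float = 0.9
) -> CpgsTable:
    """Raw cPGS: score[i, k] = sum_j W[k, j] * dosage[i, j].

    Weight variants absent from the dosage matrix are imputed with each
    sample's mean dosage over present variants (logged); if the present
    fraction drops below ``min_coverage`` this is a hard error.
    """
    w_vars = list(weights.columns)
    present = [v for v in w_vars if v in dosages.columns]
    coverage = len(present) / len(w_vars) if w_vars else 1.0
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.1%} of weight variants present in genotypes "
            f"(floor {min_coverage:.1%})"
        )
    d = dosages.reindex(columns=w_vars)
    missing = [v for v in w_vars if v not in dosages.columns]
    if missing:
        logger.warning("imputing %d missing variants with per-sample mean dosage", len(missing))
        sample_mean = dosages[present].mean(axis=1)
        for v in missing:
            d[v] = sample_mean
    raw = pd.DataFrame(
        d.to_numpy(dtype=float) @ weights.to_numpy(dtype=float).T,
        index=dosages.index,
        columns=weights.index,
    )
    return CpgsTable(raw=raw)


def standardize_scores(
    table: CpgsTable, reference: pd.DataFrame | None = None, reference_name: str = "ALL"
) -> CpgsTable:
    """Standardize per cluster against a reference cohort's raw scores.

    By default the table is its own reference (z has mean 0, SD 1 per
    cluster). Passing the full-cohort raw scores as ``reference`` keeps
    sub-cohort tables on the common scale. Top-decile flags mark scores at or
    above the reference's 90th percentile, ties included.
    """
    ref = table.raw if reference is None else reference
    mean, sd = ref.mean(axis=0), ref.std(axis=0, ddof=0)
    bad = [c for c in ref.columns if sd[c] <= 0]
    if bad:
        raise ValueError(f"zero score SD in reference cohort for cluster(s) {bad}")
    z = (table.raw - mean) / sd
    thresh = ref.quantile(0.9, axis=0, interpolation="linear")
    top = table.raw.ge(thresh, axis=1)
    return CpgsTable(raw=table.raw, z=z, top_decile=top, reference=reference_name)


def anderson_darling_normal(x: np.ndarray) -> tuple[float, float]:
    """Anderson-Darling composite normality test (parameters estimated).

    Returns the small-sample-adjusted statistic A2* = A2 (1 + 0.75/n +
    2.25/n^2) and its p-value from the Stephens case-3 piecewise
    approximation (both mean and variance estimated from the data).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 observations")
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    cdf = np.clip(cdf, 1e-15, 1 - 1e-15)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a2s = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        # the quadratic approximation is valid for moderate statistics only;
        # beyond its minimum the exponent is monotone-clamped (p ~ 0 anyway)
        exponent = 1.2937 - 5.709 * a2s + 0.0186 * a2s**2
        if a2s > 150:
            exponent = 1.2937 - 5.709 * 150 + 0.0186 * 150**2
        p = math.exp(exponent)
    elif a2s > 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return float(a2s), float(min(max(p, 0.0), 1.0))


def count_modes(
    x: np.ndarray, prominence_frac: float = 0.05, grid_size: int = 512
) -> int:
    """Count density peaks: Gaussian KDE (Silverman bandwidth), strict local
    maxima with prominence >= ``prominence_frac`` of the density maximum."""
    x = np.asarray(x, dtype=float)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    pad = 3 * kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=prominence_frac * dens.max())
    return max(int(len(peaks)), 1)


@dataclass
class DistributionReport:
    """Normality, modality and ancestry-shift tests per cluster."""

    normality: pd.DataFrame = field(default_factory=pd.DataFrame)
    ancestry_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "normality": self.normality.to_dict(orient="records"),
                "ancestry_pairs": self.ancestry_pairs.to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )


def test_distributions(
    table: CpgsTable,
    ancestry_labels: pd.Series | None = None,
    min_group: int = 20,
) -> DistributionReport:
    """Anderson-Darling normality + mode count per cluster per cohort, and
    two-sided Mann-Whitney for every ancestry pair per cluster.

    Groups below ``min_group`` samples are reported not-evaluable rather
    than tested.
    """
    if table.z is None:
        raise ValueError("standardize scores before testing distributions")
    z = table.z
    cohorts: dict[str, pd.DataFrame] = {"ALL": z}
    if ancestry_labels is not None:
        labels = ancestry_labels.reindex(z.index)
        for g in sorted(labels.dropna().unique()):
            cohorts[str(g)] = z.loc[labels == g]
    norm_rows, pair_rows = [], []
    for cluster in z.columns:
        for name, sub in cohorts.items():
            vals = sub[cluster].to_numpy()
            if len(vals) < min_group:
                norm_rows.append(
                    {"cluster": cluster, "cohort": name, "n": len(vals),
                     "ad_statistic": np.nan, "ad_p": np.nan, "n_modes": np.nan,
                     "evaluable": False}
                )
                continue
            a2, p = anderson_darling_normal(vals)
            norm_rows.append(
                {"cluster": cluster, "cohort": name, "n": len(vals),
                 "ad_statistic": a2, "ad_p": p, "n_modes": count_modes(vals),
                 "evaluable": True}
            )
        groups = [g for g in cohorts if g != "ALL"]
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = cohorts[ga][cluster].to_numpy()
                b = cohorts[gb][cluster].to_numpy()
                if len(a) < min_group or len(b) < min_group:
                    pair_rows.append({"cluster": cluster, "group_a": ga, "group_b": gb,
                                      "u_statistic": np.nan, "p": np.nan, "evaluable": False})
                    continue
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                pair_rows.append({"cluster": cluster, "group_a": ga, "group_b": gb,
                                  "u_statistic": float(u), "p": float(p), "evaluable": True})
    return DistributionReport(
        normality=pd.DataFrame(norm_rows),
        ancestry_pairs=pd.DataFrame(pair_rows),
    )


def decile_overlap(table: CpgsTable) -> dict:
    """How samples spread over the clusters' top deciles.

    Reports the fraction of samples in at least one cluster's top decile
    and, among those, the split over exactly 1, 2-3, and >= 4 clusters.
    """
    if table.top_decile is None:
        raise ValueError("top-decile flags not computed; standardize first")
    counts = table.top_decile.sum(axis=1)
    n = len(counts)
    at_risk = counts >= 1
    n_risk = int(at_risk.sum())
    denom = max(n_risk, 1)
    return {
        "n_samples": n,
        "n_at_risk": n_risk,
        "frac_ge1": n_risk / n if n else 0.0,
        "frac_exactly1_of_risk": int((counts == 1).sum()) / denom,
        "frac_2to3_of_risk": int(((counts >= 2) & (counts <= 3)).sum()) / denom,
        "frac_ge4_of_risk": int((counts >= 4).sum()) / denom,
    }


def write_plink_score_files(weights: pd.DataFrame, risk_alleles: pd.Series, outdir) -> list:
    """Write one PLINK --score-compatible (variant, allele, weight) file per cluster."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cluster in weights.index:
        path = outdir / f"score_{cluster}.txt"
        df = pd.DataFrame(
            {
                "variant_id": weights.columns,
                "allele": [risk_alleles.get(v, "A") for v in weights.columns],
                "weight": weights.loc[cluster].to_numpy(),
            }
        )
        df.to_csv(path, sep="\t", index=False, header=False)
        paths.append(path)
    return paths
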