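"""Variant-trait association ingest and factorization-input assembly.

Reads GWAS-catalog-dialect association tables, expands LD proxies back to
lead variants, aligns effect alleles to the kidney-function-decreasing
allele, applies the selection filters (gender-specific studies, small
studies, kidney-function traits, weak significance, traits with too few
variants), standardizes effects to beta = B/SE, and assembles the
non-negative matrix handed to the factorization stage.

Because B/SE is signed and NMF needs a non-negative input, each trait is
split into a "+" component row holding max(beta, 0) and a "-" component row
holding max(-beta, 0) (``sign_mode='split'``, the default); clipping and
absolute-value modes are offered for sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: filters in their fixed order of application
FILTER_RULES = ("gender_specific", "small_n", "ckd_trait", "weak_p", "rare_trait")

#: default case-insensitive patterns marking traits that *are* kidney function
DEFAULT_CKD_PATTERNS = (
    "chronic kidney",
    "glomerular filtration",
    r"\beGFR\b",
    r"\bCKD\b",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MANDATORY_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "trait",
    "beta",
    "se",
    "p_value",
    "n",
    "gender_specific",
    "study",
)


@dataclass
class AssociationRecord:
    """One variant-trait association as published (trait units)."""

    variant_id: str
    effect_allele: str
    other_allele: str
    trait_name: str
    B: float
    SE: float
    p_value: float
    study_n: int
    gender_specific: bool = False
    source_study: str = ""

    def validate(self) -> str | None:
        """Return a reason string if the record violates an invariant."""
        if not (self.SE > 0):
            return "nonpositive SE"
        if not (0 < self.p_value <= 1):
            return "p-value outside (0, 1]"
        if not self.effect_allele or not self.other_allele:
            return "empty allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        return None


def parse_catalog_associations(
    path,
) -> tuple[list[AssociationRecord], pd.DataFrame]:
    """Parse a GWAS-catalog-dialect TSV into records plus a rejects report.

    Malformed rows are collected with a reason, never silently dropped; a
    missing mandatory column is a hard error naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    records: list[AssociationRecord] = []
    reject_rows = []
    for idx, row in df.iterrows():
        try:
            rec = AssociationRecord(
                variant_id=str(row["variant_id"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                trait_name=str(row["trait"]),
                B=float(row["beta"]),
                SE=float(row["se"]),
                p_value=float(row["p_value"]),
                study_n=int(row["n"]),
                gender_specific=_parse_bool(row["gender_specific"]),
                source_study=str(row["study"]),
            )
        except (TypeError, ValueError) as exc:
            reject_rows.append({"row": idx, "reason": f"unparseable: {exc}"})
            continue
        reason = rec.validate()
        if reason is not None:
            reject_rows.append({"row": idx, "reason": reason})
        else:
            records.append(rec)
    rejects = pd.DataFrame(reject_rows, columns=["row", "reason"])
    return records, rejects


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes", "t")


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Serialize records back to the TSV column layout (round-trippable)."""
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "trait": r.trait_name,
                "beta": r.B,
                "se": r.SE,
                "p_value": r.p_value,
                "n": r.study_n,
                "gender_specific": r.gender_specific,
                "study": r.source_study,
            }
            for r in records
        ],
        columns=list(MANDATORY_COLUMNS),
    )


def expand_ld_proxies(
    leads: list[str], ld: pd.DataFrame, r2_min: float = 0.6
) -> dict[str, list[str]]:
    """Map each lead variant to its LD proxies at r^2 >= ``r2_min``.

    A lead is always its own proxy. A proxy in LD with several leads is
    assigned to the lead with the highest r^2 (ties broken by input order of
    the leads). Leads absent from the LD table map to themselves with a
    warning.
    """
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must be in [0, 1]")
    if not {"lead", "proxy", "r2"} <= set(ld.columns):
        raise ValueError("LD table needs columns lead, proxy, r2")
    if ((ld["r2"] < 0) | (ld["r2"] > 1)).any():
        raise ValueError("r2 values must lie in [0, 1]")
    lead_order = {lead: i for i, lead in enumerate(leads)}
    # best claim per proxy: (r2, -lead input order)
    claims: dict[str, tuple[float, int, str]] = {}
    known_leads = set()
    for row in ld.itertuples(index=False):
        if row.lead not in lead_order:
            continue
        known_leads.add(row.lead)
        if row.r2 < r2_min or row.proxy == row.lead:
            continue
        key = (row.r2, -lead_order[row.lead])
        if row.proxy not in claims or key > claims[row.proxy][:2]:
            claims[row.proxy] = (row.r2, -lead_order[row.lead], row.lead)
    result: dict[str, list[str]] = {lead: [lead] for lead in leads}
    for proxy, (_, _, lead) in sorted(claims.items()):
        result[lead].append(proxy)
    for lead in leads:
        if lead not in known_leads:
            logger.warning("lead %s absent from LD table; maps to itself only", lead)
    return result


def proxies_to_leads(proxy_map: dict[str, list[str]]) -> dict[str, str]:
    """Invert a lead->proxies map to proxy->lead for association attribution."""
    return {proxy: lead for lead, proxies in proxy_map.items() for proxy in proxies}


def align_effect_alleles(
    records: list[AssociationRecord], risk_allele_table: pd.DataFrame
) -> tuple[list[AssociationRecord], pd.DataFrame]:
    """Express every effect on the kidney-function-decreasing (risk) allele.

    ``risk_allele_table`` has columns ``variant_id`` and ``risk_allele``.
    Records whose effect allele is the other allele have B negated and the
    alleles swapped; a strand flip of an unambiguous pair (e.g. A/G vs T/C)
    is resolved by complementing; strand-ambiguous A/T and C/G variants that
    do not match directly are rejected, as are variants missing from the
    table.
    """
    risk = dict(
        zip(risk_allele_table["variant_id"].astype(str), risk_allele_table["risk_allele"].astype(str).str.upper())
    )
    aligned: list[AssociationRecord] = []
    reject_rows = []
    for rec in records:
        if rec.variant_id not in risk:
            reject_rows.append({"variant_id": rec.variant_id, "trait": rec.trait_name, "reason": "variant missing from risk-allele table"})
            continue
        target = risk[rec.variant_id]
        ea, oa = rec.effect_allele, rec.other_allele
        ambiguous = {ea, oa} in ({"A", "T"}, {"C", "G"})
        if ea == target:
            aligned.append(rec)
        elif oa == target:
            aligned.append(_flipped(rec))
        elif not ambiguous and _COMPLEMENT.get(ea) == target:
            aligned.append(_complemented(rec))
        elif not ambiguous and _COMPLEMENT.get(oa) == target:
            aligned.append(_flipped(_complemented(rec)))
        else:
            reason = (
                "strand-ambiguous variant with no unambiguous match"
                if ambiguous
                else "alleles do not match risk allele on either strand"
            )
            reject_rows.append({"variant_id": rec.variant_id, "trait": rec.trait_name, "reason": reason})
    rejects = pd.DataFrame(reject_rows, columns=["variant_id", "trait", "reason"])
    return aligned, rejects


def _flipped(rec: AssociationRecord) -> AssociationRecord:
    return AssociationRecord(
        variant_id=rec.variant_id,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        trait_name=rec.trait_name,
        B=-rec.B,
        SE=rec.SE,
        p_value=rec.p_value,
        study_n=rec.study_n,
        gender_specific=rec.gender_specific,
        source_study=rec.source_study,
    )


def _complemented(rec: AssociationRecord) -> AssociationRecord:
    return AssociationRecord(
        variant_id=rec.variant_id,
        effect_allele=_COMPLEMENT[rec.effect_allele],
        other_allele=_COMPLEMENT[rec.other_allele],
        trait_name=rec.trait_name,
        B=rec.B,
        SE=rec.SE,
        p_value=rec.p_value,
        study_n=rec.study_n,
        gender_specific=rec.gender_specific,
        source_study=rec.source_study,
    )


@dataclass
class FilterParams:
    """Selection thresholds; defaults are the published values."""

    p_max: float = 1e-6
    n_min: int = 100
    min_variants_per_trait: int = 5
    trait_blacklist_patterns: tuple[str, ...] = DEFAULT_CKD_PATTERNS

    def __post_init__(self) -> None:
        if self.p_max <= 0 or self.n_min <= 0 or self.min_variants_per_trait <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class FilterReport:
    """Exact, order-dependent removal counts per filter rule."""

    removed: dict[str, int] = field(default_factory=dict)
    retained_associations: int = 0
    retained_traits: int = 0
    retained_variants: int = 0
    input_associations: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed": self.removed,
                "retained_associations": self.retained_associations,
                "retained_traits": self.retained_traits,
                "retained_variants": self.retained_variants,
                "input_associations": self.input_associations,
            },
            indent=2,
        )


def apply_filters(
    records: list[AssociationRecord], params: FilterParams | None = None
) -> tuple[list[AssociationRecord], FilterReport]:
    """Apply the selection filters in fixed order and count removals exactly.

    Order: gender_specific -> small_n -> ckd_trait -> weak_p -> rare_trait.
    ``rare_trait`` (fewer than ``min_variants_per_trait`` distinct variants)
    is computed last, on the records surviving the other rules, because its
    trigger depends on prior removals. An empty retained set is valid.
    """
    params = params or FilterParams()
    patterns = [re.compile(p, re.IGNORECASE) for p in params.trait_blacklist_patterns]
    report = FilterReport(removed={r: 0 for r in FILTER_RULES}, input_associations=len(records))

    current = records
    for rule in ("gender_specific", "small_n", "ckd_trait", "weak_p"):
        keep: list[AssociationRecord] = []
        for rec in current:
            if rule == "gender_specific":
                bad = rec.gender_specific
            elif rule == "small_n":
                bad = rec.study_n < params.n_min
            elif rule == "ckd_trait":
                bad = any(p.search(rec.trait_name) for p in patterns)
            else:  # weak_p: keep strictly below the significance threshold
                bad = not (rec.p_value < params.p_max)
            if bad:
                report.removed[rule] += 1
            else:
                keep.append(rec)
        current = keep

    counts: dict[str, set[str]] = {}
    for rec in current:
        counts.setdefault(rec.trait_name, set()).add(rec.variant_id)
    rare = {t for t, vs in counts.items() if len(vs) < params.min_variants_per_trait}
    retained = [r for r in current if r.trait_name not in rare]
    report.removed["rare_trait"] = len(current) - len(retained)
    report.retained_associations = len(retained)
    report.retained_traits = len({r.trait_name for r in retained})
    report.retained_variants = len({r.variant_id for r in retained})
    return retained, report


def standardize_effect(record: AssociationRecord) -> float:
    """Standardized effect beta = B / SE (sign preserved)."""
    if record.SE <= 0:
        raise ValueError("SE must be positive")
    return record.B / record.SE


@dataclass
class EffectMatrix:
    """Non-negative trait-component x variant matrix of standardized effects.

    Rows are trait sign components labelled ``trait|+`` / ``trait|-`` in
    split mode (one row per trait otherwise); the sign registry maps each
    row label to its direction so cluster summaries can report signed
    effects after factorization.
    """

    row_labels: list[str]
    variant_ids: list[str]
    values: np.ndarray
    sign_registry: dict[str, str]
    build_params: dict = field(default_factory=dict)

    @property
    def trait_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.row_labels:
            seen.setdefault(label.rsplit("|", 1)[0], None)
        return list(seen)

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.variant_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="component")

    @classmethod
    def from_tsv(cls, path) -> "EffectMatrix":
        df = pd.read_csv(path, sep="\t", index_col="component")
        registry = {
            label: (label.rsplit("|", 1)[1] if "|" in label else "+") for label in df.index
        }
        return cls(
            row_labels=list(df.index),
            variant_ids=list(df.columns),
            values=df.to_numpy(dtype=float),
            sign_registry=registry,
        )


def build_matrix(
    records: list[AssociationRecord], sign_mode: str = "split"
) -> EffectMatrix:
    """Assemble the non-negative factorization input from filtered records.

    Duplicate (trait, variant) pairs keep the smallest p-value (collision
    logged). ``split`` mode emits per trait a "+" row of max(beta, 0) and a
    "-" row of max(-beta, 0), dropping empty components; ``clip`` zeroes
    negatives; ``abs`` takes magnitudes. Rows and columns are ordered
    lexicographically for determinism.
    """
    if sign_mode not in ("split", "clip", "abs"):
        raise ValueError("sign_mode must be one of split, clip, abs")
    best: dict[tuple[str, str], AssociationRecord] = {}
    for rec in records:
        key = (rec.trait_name, rec.variant_id)
        if key in best:
            logger.info("duplicate association for %s; keeping smaller p", key)
            if rec.p_value < best[key].p_value:
                best[key] = rec
        else:
            best[key] = rec

    traits = sorted({t for t, _ in best})
    variants = sorted({v for _, v in best})
    t_idx = {t: i for i, t in enumerate(traits)}
    v_idx = {v: j for j, v in enumerate(variants)}
    beta = np.zeros((len(traits), len(variants)))
    for (t, v), rec in best.items():
        beta[t_idx[t], v_idx[v]] = standardize_effect(rec)

    rows, labels, registry = [], [], {}
    for i, t in enumerate(traits):
        if sign_mode == "split":
            pos, neg = np.maximum(beta[i], 0.0), np.maximum(-beta[i], 0.0)
            if pos.any():
                labels.append(f"{t}|+")
                registry[f"{t}|+"] = "+"
                rows.append(pos)
            if neg.any():
                labels.append(f"{t}|-")
                registry[f"{t}|-"] = "-"
                rows.append(neg)
        elif sign_mode == "clip":
            labels.append(t)
            registry[t] = "+"
            rows.append(np.maximum(beta[i], 0.0))
        else:
            labels.append(t)
            registry[t] = "+"
            rows.append(np.abs(beta[i]))
    values = np.vstack(rows) if rows else np.empty((0, len(variants)))
    return EffectMatrix(
        row_labels=labels,
        variant_ids=variants,
        values=values,
        sign_registry=registry,
        build_params={"sign_mode": sign_mode},
    )


def sweep_min_variants(
    records: list[AssociationRecord],
    thresholds=range(2, 16),
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Retained trait/variant/association counts as the sparsity threshold varies.

    The minimum-variants-per-trait cut was chosen empirically in the study
    design; this utility reproduces that sensitivity sweep rather than
    automating the choice.
    """
    base = params or FilterParams()
    rows = []
    for m in thresholds:
        p = FilterParams(
            p_max=base.p_max,
            n_min=base.n_min,
            min_variants_per_trait=m,
            trait_blacklist_patterns=base.trait_blacklist_patterns,
        )
        _, rep = apply_filters(records, p)
        rows.append(
            {
                "min_variants_per_trait": m,
                "retained_associations": rep.retained_associations,
                "retained_traits": rep.retained_traits,
                "retained_variants": rep.retained_variants,
            }
        )
    return pd.DataFrame(rows)
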