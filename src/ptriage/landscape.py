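"""ClinVar-versus-cohort representation landscape.

Groups ClinVar-style aggregate classifications, determines which classified
variants are represented in the cohort, bins them by allele frequency and
allele count, assigns gene-level inheritance patterns, and computes the
mean number of pathogenic alleles carried per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .variants import GeneInfo, VariantRecord, pct, round_half_away

CLASSIFICATION_GROUPS = ("P_LP", "VUS", "B_LB", "Conflicting")

_CLASS_MAP = {
    "benign": "B_LB",
    "likely benign": "B_LB",
    "benign/likely benign": "B_LB",
    "uncertain significance": "VUS",
    "pathogenic": "P_LP",
    "likely pathogenic": "P_LP",
    "pathogenic/likely pathogenic": "P_LP",
    "conflicting interpretations of pathogenicity": "Conflicting",
}

AF_BIN_LABELS = ("<0.0001", "0.0001-0.001", "0.001-0.01", "0.01-0.1", ">=0.1")
AC_BIN_LABELS = ("1", "2-5", "6-10", "11-100", ">100")

_CANONICAL_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


def map_clinvar_classification(raw_significance: str) -> str:
    """Aggregate classification group; anything unrecognized is Excluded."""
    return _CLASS_MAP.get((raw_significance or "").strip().lower(), "Excluded")


def is_present_in_cohort(variant: VariantRecord) -> bool:
    """Represented in at least one individual: a QC pass in either call set
    and a total allele count of at least one."""
    passed = bool(variant.pass_exomes) or bool(variant.pass_genomes)
    return passed and variant.total_ac >= 1


def assign_inheritance(gene_info: GeneInfo | None) -> str:
    """AR / AD / AR_AD / XL from the reported gene-level patterns; genes with
    no usable pattern are Excluded from the inheritance analysis."""
    if gene_info is None:
        return "Excluded"
    p = gene_info.omim_patterns
    has_ad, has_ar = "AD" in p, "AR" in p
    if has_ad and has_ar:
        return "AR_AD"
    if has_ad:
        return "AD"
    if has_ar:
        return "AR"
    if "XL" in p:
        return "XL"
    return "Excluded"


def bin_allele_frequency(af: float) -> str:
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency out of [0,1]: {af}")
    if af < 1e-4:
        return AF_BIN_LABELS[0]
    if af < 1e-3:
        return AF_BIN_LABELS[1]
    if af < 1e-2:
        return AF_BIN_LABELS[2]
    if af < 1e-1:
        return AF_BIN_LABELS[3]
    return AF_BIN_LABELS[4]


def bin_allele_count(ac: int) -> str:
    if ac < 1:
        raise ValueError(f"allele count must be >= 1, got {ac}")
    if ac == 1:
        return AC_BIN_LABELS[0]
    if ac <= 5:
        return AC_BIN_LABELS[1]
    if ac <= 10:
        return AC_BIN_LABELS[2]
    if ac <= 100:
        return AC_BIN_LABELS[3]
    return AC_BIN_LABELS[4]


def passes_ingest_filter(variant: VariantRecord, max_indel_bp: int = 50) -> bool:
    """SNVs and indels shorter than 50 bp; canonical-chromosome filtering is
    applied only when contig names look like human chromosomes."""
    if max(len(variant.ref), len(variant.alt)) - 1 >= max_indel_bp:
        return False
    contig = variant.contig.removeprefix("chr")
    if contig.upper() in _CANONICAL_CHROMS or (
        variant.contig.startswith("chr") and contig.isalnum() and len(contig) <= 2
    ):
        return contig.upper() in _CANONICAL_CHROMS
    return True


@dataclass
class LandscapeSummary:
    """Per-classification-group representation plus frequency histograms."""

    totals: dict[str, int] = field(default_factory=dict)
    present: dict[str, int] = field(default_factory=dict)
    percent_present: dict[str, float] = field(default_factory=dict)
    af_hist: dict[str, dict[str, int]] = field(default_factory=dict)
    ac_hist_plp: dict[str, int] = field(default_factory=dict)
    inheritance_hist: dict[str, int] = field(default_factory=dict)
    burden: float = 0.0
    n_individuals: int = 0

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "present": self.present,
            "percent_present": self.percent_present,
            "af_hist": self.af_hist,
            "ac_hist_plp": self.ac_hist_plp,
            "inheritance_hist": self.inheritance_hist,
            "burden": self.burden,
            "n_individuals": self.n_individuals,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in CLASSIFICATION_GROUPS:
            rows.append(
                {
                    "group": g,
                    "total": self.totals.get(g, 0),
                    "present": self.present.get(g, 0),
                    "percent_present": self.percent_present.get(g, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def pathogenic_allele_burden(total_alleles: int, n_individuals: int) -> float:
    """Mean pathogenic alleles per individual, one-decimal rounding."""
    if n_individuals <= 0:
        raise ValueError("zero individuals")
    return round_half_away(total_alleles / n_individuals, 1)


def summarize_landscape(
    clinvar: pd.DataFrame,
    variants: list[VariantRecord],
    n_individuals: int,
    gene_info: dict[str, GeneInfo] | None = None,
) -> LandscapeSummary:
    """Cross the ClinVar-like table with the cohort variant set.

    ``clinvar`` needs columns ``variant_id``, ``clinical_significance`` and
    optionally ``gene``.  Presence, AF/AC binning and the pathogenic-allele
    burden are computed from the cohort records.
    """
    if n_individuals <= 0:
        raise ValueError("zero individuals")
    by_id = {
        v.variant_id: v for v in variants if passes_ingest_filter(v)
    }
    summary = LandscapeSummary(n_individuals=n_individuals)
    for g in CLASSIFICATION_GROUPS:
        summary.totals[g] = 0
        summary.present[g] = 0
        summary.af_hist[g] = {label: 0 for label in AF_BIN_LABELS}
    summary.ac_hist_plp = {label: 0 for label in AC_BIN_LABELS}
    plp_allele_total = 0
    for row in clinvar.itertuples(index=False):
        group = map_clinvar_classification(row.clinical_significance)
        if group == "Excluded":
            continue
        summary.totals[group] += 1
        v = by_id.get(row.variant_id)
        if v is None or not is_present_in_cohort(v):
            continue
        summary.present[group] += 1
        summary.af_hist[group][bin_allele_frequency(v.combined_af())] += 1
        if group == "P_LP":
            summary.ac_hist_plp[bin_allele_count(v.total_ac)] += 1
            plp_allele_total += v.total_ac
            if gene_info is not None:
                gene = getattr(row, "gene", None)
                pattern = assign_inheritance(gene_info.get(gene) if gene else None)
                summary.inheritance_hist[pattern] = (
                    summary.inheritance_hist.get(pattern, 0) + 1
                )
    for g in CLASSIFICATION_GROUPS:
        if summary.totals[g] > 0:
            summary.percent_present[g] = pct(summary.present[g], summary.totals[g])
    summary.burden = pathogenic_allele_burden(plp_allele_total, n_individuals)
    return summary
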