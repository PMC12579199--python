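"""Cis-modifier rescue scan.

Searches for pathogenic/likely-pathogenic variants whose carriers also carry
a rare pLoF variant in the same gene — a configuration that can convert a
dominant-negative or gain-of-function allele into a simple loss-of-function
allele and thereby explain the absence of disease.  A candidate pair is
"interesting" when (1) more than half of the P/LP carriers co-carry the
modifier, (2) the modifier is curated as a genuine LoF, and (3) the P/LP
variant acts through a dominant gain-of-function mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import Thresholds
from .curation import CurationResult
from .variants import GenotypeCall, GeneInfo, Sample, VariantRecord

GOF_MECHANISMS = {"gof", "gain_of_function", "gain-of-function", "dominant_negative",
                  "dominant-negative"}


def select_candidate_plp(
    variant: VariantRecord,
    gene_info: GeneInfo | None,
    thr: Thresholds | None = None,
) -> bool:
    """P/LP, rare (AC <= 50), in a LoF-tolerant gene (pLI < 0.9) with at
    least one autosomal-dominant condition reported."""
    thr = thr or Thresholds()
    from .landscape import map_clinvar_classification

    if variant.clinvar_class is None:
        return False
    if map_clinvar_classification(variant.clinvar_class) != "P_LP":
        return False
    if variant.total_ac > thr.plp_ac_max:
        return False
    if gene_info is None or gene_info.pli is None:
        return False
    if gene_info.pli >= thr.plp_pli_max:
        return False
    return "AD" in gene_info.omim_patterns


def genotype_passes_qc(call: GenotypeCall, thr: Thresholds | None = None) -> bool:
    """Genotype-level QC: fails on depth < 10, genotype quality < 20, or
    heterozygous allele balance < 0.2 (boundaries pass)."""
    thr = thr or Thresholds()
    if call.dp is None or call.gq is None:
        return False
    if call.dp < thr.qc_dp_min or call.gq < thr.qc_gq_min:
        return False
    if call.gt == "het":
        ab = call.allele_balance()
        if ab is None or ab < thr.qc_ab_min:
            return False
    return True


@dataclass
class RescueCandidate:
    plp_variant_id: str
    modifier_variant_id: str
    carrier_count: int
    co_carrier_count: int
    ancestry_breakdown: dict[str, int] = field(default_factory=dict)
    phase_support: str = "unknown"  # cis_confirmed | unknown
    criterion_fraction: bool = False
    criterion_modifier_lof: bool = False
    criterion_gof_mechanism: bool = False

    @property
    def cooccurrence_fraction(self) -> float:
        return self.co_carrier_count / self.carrier_count

    @property
    def interesting(self) -> bool:
        return (
            self.criterion_fraction
            and self.criterion_modifier_lof
            and self.criterion_gof_mechanism
        )


def qc_carriers(
    variant_id: str,
    genotypes: dict[str, dict[str, GenotypeCall]],
    thr: Thresholds,
) -> dict[str, GenotypeCall]:
    return {
        sid: call
        for sid, call in genotypes.get(variant_id, {}).items()
        if call.is_carrier and genotype_passes_qc(call, thr)
    }


def scan_modifiers(
    plp_variant: VariantRecord,
    gene_plofs: list[VariantRecord],
    genotypes: dict[str, dict[str, GenotypeCall]],
    samples_by_id: dict[str, Sample],
    curation_results: dict[str, CurationResult],
    mechanism: str,
    thr: Thresholds | None = None,
) -> list[RescueCandidate]:
    """All (P/LP, modifier) candidates for one P/LP variant.

    ``gene_plofs`` are the pLoF variants of the same gene; modifiers above
    the global-AF cap (combined AF > 1%) are excluded.  One candidate is
    emitted per modifier with at least one co-carrier.
    """
    thr = thr or Thresholds()
    plp_carriers = qc_carriers(plp_variant.variant_id, genotypes, thr)
    if not plp_carriers:
        return []
    breakdown: dict[str, int] = {}
    for sid in plp_carriers:
        grp = samples_by_id[sid].ancestry_group if sid in samples_by_id else "unknown"
        breakdown[grp] = breakdown.get(grp, 0) + 1
    out = []
    for modifier in gene_plofs:
        if modifier.variant_id == plp_variant.variant_id:
            continue
        if modifier.combined_af() > thr.modifier_af_max:
            continue
        mod_carriers = qc_carriers(modifier.variant_id, genotypes, thr)
        co = set(plp_carriers) & set(mod_carriers)
        if not co:
            continue
        phase = "unknown"
        for sid in co:
            a, b = plp_carriers[sid], mod_carriers[sid]
            if (
                a.phase_partner == modifier.variant_id
                or b.phase_partner == plp_variant.variant_id
            ):
                phase = "cis_confirmed"
                break
        curated = curation_results.get(modifier.variant_id)
        cand = RescueCandidate(
            plp_variant_id=plp_variant.variant_id,
            modifier_variant_id=modifier.variant_id,
            carrier_count=len(plp_carriers),
            co_carrier_count=len(co),
            ancestry_breakdown=breakdown,
            phase_support=phase,
            criterion_fraction=len(co) / len(plp_carriers) > thr.cooccurrence_min,
            criterion_modifier_lof=(
                curated is not None and curated.outcome == "unexplained"
            ),
            criterion_gof_mechanism=(mechanism or "").strip().lower()
            in GOF_MECHANISMS,
        )
        out.append(cand)
    return out


def scan_cohort(
    variants: list[VariantRecord],
    genotypes: dict[str, dict[str, GenotypeCall]],
    samples_by_id: dict[str, Sample],
    gene_info: dict[str, GeneInfo],
    curation_results: dict[str, CurationResult],
    mechanisms: dict[str, str],
    thr: Thresholds | None = None,
) -> list[RescueCandidate]:
    """Run the scan over every candidate P/LP variant in the cohort.

    ``mechanisms`` maps variant_id -> reported disease mechanism
    (GoF / dominant-negative / LoF / unknown)."""
    thr = thr or Thresholds()
    plofs_by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        for c in v.consequences:
            if c.is_plof:
                plofs_by_gene.setdefault(c.gene, []).append(v)
                break
    out: list[RescueCandidate] = []
    for v in variants:
        genes = {c.gene for c in v.consequences}
        info = next((gene_info[g] for g in genes if g in gene_info), None)
        if not select_candidate_plp(v, info, thr):
            continue
        pool = [p for g in genes for p in plofs_by_gene.get(g, [])]
        out.extend(
            scan_modifiers(
                v, pool, genotypes, samples_by_id, curation_results,
                mechanisms.get(v.variant_id, "unknown"), thr,
            )
        )
    return out
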