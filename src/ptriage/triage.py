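"""Post-curation triage of unexplained pLoF variants.

The filtering cascade applied to curation-unexplained variants and their
carriers: (1) exclusion of carriers from a project suspected of cell-line
somatic artifacts, with variants dropped once carrier-less; (2) removal of
variants with intermediate allele balance (median carrier AB < 35%) and/or
in clonal-hematopoiesis genes, both signatures of somatic origin; (3)
removal of variants absent from MANE Select transcripts.  Carrier-age skew
toward elderly individuals — the epidemiological footprint of age-related
clonal hematopoiesis — is tested with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from statistics import median

import numpy as np
from scipy.stats import norm, rankdata

from .config import Thresholds
from .variants import GenotypeCall, GeneInfo, Sample, VariantRecord

# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(
    group_a, group_b, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic of ``group_a`` (midranks for ties) and a
    two-sided p-value: exact by enumeration of rank assignments when the
    smaller group has at most ``exact_max_n`` observations and there are no
    ties, otherwise a normal approximation with tie-corrected variance and
    a continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < n
    if min(n_a, n_b) <= exact_max_n and not has_ties:
        # enumerate every assignment of n_a ranks out of 1..n
        target = abs(w - mu) - 1e-9
        m = min(n_a, n_b)
        count = total = 0
        for combo in combinations(range(1, n + 1), m):
            total += 1
            w_small = sum(combo)
            # statistic for the smaller group; symmetric around its own mean
            mu_small = m * (n + 1) / 2.0
            if abs(w_small - mu_small) >= target:
                count += 1
        return w, count / total
    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = max(abs(w - mu) - 0.5, 0.0) / math.sqrt(var)
    return w, min(1.0, 2.0 * norm.sf(z))


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class TriageReport:
    """Stage-by-stage cascade counts, per-variant flags and age-skew tests."""

    stages: list[dict] = field(default_factory=list)
    flags: dict[str, dict[str, bool]] = field(default_factory=dict)
    drop_reason: dict[str, str] = field(default_factory=dict)
    age_tests: dict[str, dict] = field(default_factory=dict)
    surviving_variants: list[str] = field(default_factory=list)

    def add_stage(self, name: str, carriers: dict[str, set[str]]) -> None:
        self.stages.append(
            {
                "stage": name,
                "variants": len(carriers),
                "carriers": len(set().union(*carriers.values()) if carriers else set()),
            }
        )

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "flags": {k: dict(v) for k, v in self.flags.items()},
            "drop_reason": dict(self.drop_reason),
            "age_tests": self.age_tests,
            "surviving_variants": list(self.surviving_variants),
        }


def exclude_project(
    variant_carriers: dict[str, set[str]],
    samples_by_id: dict[str, Sample],
    project_label: str,
) -> tuple[dict[str, set[str]], set[str]]:
    """Remove carriers from the named project; drop variants left with no
    carriers.  Unknown project labels leave the input unchanged."""
    known = {s.project for s in samples_by_id.values()}
    if project_label not in known:
        import warnings

        warnings.warn(f"project label {project_label!r} not found; no-op")
        return {k: set(v) for k, v in variant_carriers.items()}, set()
    dropped: set[str] = set()
    out: dict[str, set[str]] = {}
    for vid, carriers in variant_carriers.items():
        kept = {
            sid
            for sid in carriers
            if sid in samples_by_id and samples_by_id[sid].project != project_label
        }
        if kept:
            out[vid] = kept
        else:
            dropped.add(vid)
    return out, dropped


def median_carrier_ab(calls: list[GenotypeCall]) -> float | None:
    abs_ = [ab for c in calls if (ab := c.allele_balance()) is not None]
    return median(abs_) if abs_ else None


def run_triage(
    unexplained: list[VariantRecord],
    genotypes: dict[str, dict[str, GenotypeCall]],
    samples: list[Sample],
    gene_info: dict[str, GeneInfo],
    mane_transcripts: set[str],
    excluded_project: str,
    thr: Thresholds | None = None,
) -> TriageReport:
    """Apply the full cascade to curation-unexplained variants."""
    thr = thr or Thresholds()
    samples_by_id = {s.sample_id: s for s in samples}
    report = TriageReport()
    by_id = {v.variant_id: v for v in unexplained}
    carriers = {
        v.variant_id: {
            sid for sid, c in genotypes.get(v.variant_id, {}).items() if c.is_carrier
        }
        for v in unexplained
    }
    carriers = {k: v for k, v in carriers.items() if v}
    report.add_stage("unexplained", carriers)

    carriers, dropped = exclude_project(carriers, samples_by_id, excluded_project)
    for vid in dropped:
        report.drop_reason[vid] = "excluded_project_only"
    report.add_stage("after_project_exclusion", carriers)

    # somatic signatures: intermediate AB and clonal-hematopoiesis genes
    survivors: dict[str, set[str]] = {}
    for vid, sids in carriers.items():
        v = by_id[vid]
        calls = [genotypes[vid][sid] for sid in sids]
        med_ab = median_carrier_ab(calls)
        ab_flag = med_ab is not None and med_ab < thr.ab_triage_max
        genes = {c.gene for c in v.consequences}
        ch_flag = any(
            gene_info[g].is_ch_gene for g in genes if g in gene_info
        )
        report.flags[vid] = {
            "excluded_project_only": False,
            "ab_under_35": ab_flag,
            "ch_gene": ch_flag,
            "non_mane": False,
        }
        if ab_flag or ch_flag:
            report.drop_reason[vid] = (
                "ab_under_35" if ab_flag and not ch_flag
                else "ch_gene" if ch_flag and not ab_flag
                else "ab_under_35+ch_gene"
            )
        else:
            survivors[vid] = sids
    for vid in dropped:
        report.flags[vid] = {
            "excluded_project_only": True,
            "ab_under_35": False,
            "ch_gene": False,
            "non_mane": False,
        }
    carriers = survivors
    report.add_stage("after_somatic_filters", carriers)

    # MANE Select membership
    survivors = {}
    for vid, sids in carriers.items():
        v = by_id[vid]
        on_mane = any(c.transcript_id in mane_transcripts for c in v.consequences)
        if on_mane:
            survivors[vid] = sids
        else:
            report.flags[vid]["non_mane"] = True
            report.drop_reason[vid] = "non_mane"
    carriers = survivors
    report.add_stage("final_unexplained", carriers)
    report.surviving_variants = sorted(carriers)

    # age-skew tests per somatic flag group (carriers after project exclusion)
    for flag in ("ab_under_35", "ch_gene"):
        flagged_sids: set[str] = set()
        for vid, f in report.flags.items():
            if f.get(flag):
                flagged_sids |= {
                    sid
                    for sid, c in genotypes.get(vid, {}).items()
                    if c.is_carrier
                    and sid in samples_by_id
                    and samples_by_id[sid].project != excluded_project
                }
        ages_flagged = [
            samples_by_id[sid].age
            for sid in flagged_sids
            if samples_by_id[sid].age is not None
        ]
        ages_rest = [
            s.age
            for s in samples
            if s.sample_id not in flagged_sids and s.age is not None
        ]
        if ages_flagged and ages_rest:
            stat, p = wilcoxon_rank_sum(ages_flagged, ages_rest)
            report.age_tests[flag] = {
                "statistic": stat,
                "p_two_sided": p,
                "n_flagged": len(ages_flagged),
                "n_rest": len(ages_rest),
            }
    return report
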