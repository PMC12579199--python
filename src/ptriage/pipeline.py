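"""End-to-end orchestration and machine-readable run reports.

Stages run in a fixed order — landscape, curation, cis-rescue scan, triage,
sQTL — writing intermediate tables along the way; a :class:`RunReport`
collects the per-stage tallies, verdict/outcome percentages, the ranked
explanation-category table and, when reference tallies are supplied, prior
evasion-rate comparisons.  Runs are deterministic for a fixed config+seed.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .curation import (
    CurationEngine,
    CurationResult,
    category_frequency_table,
    outcome_tallies,
)
from .io import Cohort, load_cohort
from .landscape import summarize_landscape
from .rescue import scan_cohort
from .sqtl import fit_exon_sqtl, flag_sqtl_overlap
from .triage import run_triage
from .variants import pct


def outcome_percentages(tallies: dict[str, int]) -> dict[str, float]:
    """Explained/uncertain/unexplained percentages of curated variants."""
    total = sum(tallies.values())
    if total == 0:
        return {}
    return {k: pct(v, total) for k, v in tallies.items()}


def evasion_rate(n_evading: int, n_total: int) -> float:
    """Percent of pLoF variants with an identified evasion mechanism."""
    return pct(n_evading, n_total)


def compare_to_truth(
    results: dict[str, CurationResult], truth: pd.DataFrame
) -> dict:
    """Score curated outcomes against the generator's truth table.

    Rows whose expected outcome is 'NA' (non-pLoF plants such as the P/LP
    missense or the sQTL variant) are skipped.  For explained rows with a
    stated category, the category must match as well.
    """
    n_checked = n_matched = 0
    mismatches = []
    for row in truth.itertuples(index=False):
        if row.expected_outcome not in ("explained", "uncertain", "unexplained"):
            continue
        n_checked += 1
        res = results.get(row.variant_id)
        ok = res is not None and res.outcome == row.expected_outcome
        if ok and row.expected_category not in ("", "NA"):
            ok = res.category == row.expected_category
        if ok and row.expected_verdict not in ("", "NA"):
            ok = res.verdict == row.expected_verdict
        if ok:
            n_matched += 1
        else:
            mismatches.append(
                {
                    "variant_id": row.variant_id,
                    "scenario": row.scenario,
                    "expected": (
                        row.expected_verdict, row.expected_category,
                        row.expected_outcome,
                    ),
                    "got": None
                    if res is None
                    else (res.verdict, res.category, res.outcome),
                }
            )
    return {
        "n_checked": n_checked,
        "n_matched": n_matched,
        "recovery_pct": pct(n_matched, n_checked) if n_checked else None,
        "mismatches": mismatches,
    }


@dataclass
class RunReport:
    seed: int
    config: dict
    landscape: dict = field(default_factory=dict)
    n_curated: int = 0
    outcome_tallies: dict = field(default_factory=dict)
    outcome_percentages: dict = field(default_factory=dict)
    category_table: dict = field(default_factory=dict)
    rescue_candidates: list = field(default_factory=list)
    n_interesting_rescues: int = 0
    triage: dict = field(default_factory=dict)
    sqtl_n_hits: int = 0
    sqtl_top_hit: dict = field(default_factory=dict)
    sqtl_flags: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    prior_comparison: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "landscape": self.landscape,
            "n_curated": self.n_curated,
            "outcome_tallies": self.outcome_tallies,
            "outcome_percentages": self.outcome_percentages,
            "category_table": self.category_table,
            "rescue_candidates": self.rescue_candidates,
            "n_interesting_rescues": self.n_interesting_rescues,
            "triage": self.triage,
            "sqtl_n_hits": self.sqtl_n_hits,
            "sqtl_top_hit": self.sqtl_top_hit,
            "sqtl_flags": self.sqtl_flags,
            "recovery": self.recovery,
            "prior_comparison": self.prior_comparison,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))


def _log(msg: str, t0: float) -> None:
    print(f"[ptriage +{time.perf_counter() - t0:6.2f}s] {msg}", file=sys.stderr)


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | str | Path,
    out_dir: str | Path | None = None,
    reference_tallies: dict[str, tuple[int, int]] | None = None,
) -> RunReport:
    """Run every stage over a cohort (a loaded bundle or a directory).

    ``reference_tallies`` optionally maps a label to (n_evading, n_total)
    pairs from prior variant sets for evasion-rate comparison.
    """
    t0 = time.perf_counter()
    if not isinstance(cohort, Cohort):
        cohort = load_cohort(cohort)
        _log("cohort loaded", t0)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, config=config.to_dict())

    # 1. landscape
    an_ex = max((v.an_exomes or 0) for v in cohort.variants) if cohort.variants else 0
    n_individuals = len(cohort.samples) + an_ex // 2
    if len(cohort.clinvar) and n_individuals:
        summary = summarize_landscape(
            cohort.clinvar, cohort.variants, n_individuals, cohort.gene_info
        )
        report.landscape = summary.to_dict()
        if out is not None:
            summary.to_frame().to_csv(out / "landscape.tsv", sep="\t", index=False)
            (out / "landscape.json").write_text(
                json.dumps(summary.to_dict(), indent=2, sort_keys=True)
            )
    _log("landscape done", t0)

    # 2. curation
    engine = CurationEngine(
        transcripts=cohort.transcripts,
        reference=cohort.reference,
        pext=cohort.pext,
        splice=cohort.splice,
        genotypes=cohort.genotypes,
        variants=cohort.variants,
        thresholds=config.thresholds,
    )
    results = engine.curate_all()
    report.n_curated = len(results)
    report.outcome_tallies = outcome_tallies(results)
    report.outcome_percentages = outcome_percentages(report.outcome_tallies)
    report.category_table = category_frequency_table(results)
    if out is not None:
        rows = [
            {
                "variant_id": r.variant_id,
                "transcript_id": r.transcript_id,
                "verdict": r.verdict,
                "outcome": r.outcome,
                "category": r.category or "",
                "fired_rules": ";".join(x.rule_id for x in r.fired()),
                "evidence": ";".join(
                    f"{x.rule_id}:{x.evidence}" for x in r.fired()
                ),
            }
            for r in results.values()
        ]
        pd.DataFrame(
            rows,
            columns=[
                "variant_id", "transcript_id", "verdict", "outcome",
                "category", "fired_rules", "evidence",
            ],
        ).to_csv(out / "curation.tsv", sep="\t", index=False)
    _log(f"curation done ({len(results)} variants)", t0)

    # 3. cis-rescue scan
    mechanisms = {}
    if "mechanism" in cohort.clinvar.columns:
        mechanisms = dict(
            zip(cohort.clinvar["variant_id"], cohort.clinvar["mechanism"])
        )
    candidates = scan_cohort(
        cohort.variants, cohort.genotypes, cohort.samples_by_id,
        cohort.gene_info, results, mechanisms, config.thresholds,
    )
    report.rescue_candidates = [
        {
            "plp_variant_id": c.plp_variant_id,
            "modifier_variant_id": c.modifier_variant_id,
            "carrier_count": c.carrier_count,
            "co_carrier_count": c.co_carrier_count,
            "cooccurrence_fraction": c.cooccurrence_fraction,
            "ancestry_breakdown": c.ancestry_breakdown,
            "phase_support": c.phase_support,
            "criteria": [
                c.criterion_fraction, c.criterion_modifier_lof,
                c.criterion_gof_mechanism,
            ],
            "interesting": c.interesting,
        }
        for c in candidates
    ]
    report.n_interesting_rescues = sum(c.interesting for c in candidates)
    if out is not None:
        pd.DataFrame(report.rescue_candidates).to_csv(
            out / "rescue.tsv", sep="\t", index=False
        )
    _log(f"rescue scan done ({len(candidates)} candidates)", t0)

    # 4. triage of unexplained variants
    by_id = cohort.variants_by_id()
    unexplained = [
        by_id[vid] for vid, r in results.items()
        if r.outcome == "unexplained" and vid in by_id
    ]
    mane = {
        t.transcript_id for t in cohort.transcripts.values() if t.mane_select
    }
    triage_report = run_triage(
        unexplained, cohort.genotypes, cohort.samples, cohort.gene_info,
        mane, config.excluded_project, config.thresholds,
    )
    report.triage = triage_report.to_dict()
    if out is not None:
        (out / "triage.json").write_text(
            json.dumps(report.triage, indent=2, sort_keys=True)
        )
    _log("triage done", t0)

    # 5. sQTL association and overlap flags
    if not cohort.psi.empty and not cohort.dosages.empty:
        hits, table = fit_exon_sqtl(
            cohort.psi, cohort.dosages,
            window_bp=config.thresholds.sqtl_window_bp,
            fdr=config.thresholds.sqtl_fdr,
        )
        plofs = [by_id[vid] for vid in results if vid in by_id]
        flags = flag_sqtl_overlap(plofs, hits, cohort.pext, cohort.genotypes)
        report.sqtl_n_hits = len(hits)
        if hits:
            h = hits[0]
            report.sqtl_top_hit = {
                "exon_id": h.exon_id, "variant_id": h.variant_id,
                "rho": h.statistic, "p": h.p, "q": h.q,
                "direction": h.direction,
            }
        report.sqtl_flags = {
            vid: {
                "sqtl_variant_id": f.sqtl_variant_id,
                "exon_id": f.exon_id,
                "q": f.q,
                "carrier_genotypes": f.carrier_genotypes,
                "pext_concordant": f.pext_concordant,
            }
            for vid, f in flags.items()
        }
        if out is not None:
            table.to_csv(out / "sqtl_pairs.tsv", sep="\t", index=False)
            pd.DataFrame(
                [dict(variant_id=k, **v) for k, v in report.sqtl_flags.items()]
            ).to_csv(out / "sqtl_flags.tsv", sep="\t", index=False)
        _log(f"sQTL done ({len(hits)} hits)", t0)

    # recovery against the planted truth, when available
    if len(cohort.truth):
        report.recovery = compare_to_truth(results, cohort.truth)

    if reference_tallies:
        this_rate = (
            evasion_rate(
                report.outcome_tallies.get("explained", 0), report.n_curated
            )
            if report.n_curated
            else None
        )
        report.prior_comparison = {"this_set": this_rate}
        for label, (n_ev, n_tot) in reference_tallies.items():
            report.prior_comparison[label] = evasion_rate(n_ev, n_tot)

    if out is not None:
        (out / "report.json").write_text(report.to_json())
        (out / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: RunReport) -> str:
    """Human-readable run summary with the ranked category table."""
    lines = [
        "ptriage run summary",
        "===================",
        f"seed: {report.seed}",
        "",
        f"curated pLoF variants: {report.n_curated}",
    ]
    if report.outcome_tallies:
        for k in ("explained", "uncertain", "unexplained"):
            n = report.outcome_tallies.get(k, 0)
            p = report.outcome_percentages.get(k)
            lines.append(
                f"  {k:12s} {n:5d}" + (f"  ({p}%)" if p is not None else "")
            )
    lines += ["", "explanation categories (ranked):"]
    for cat, n in report.category_table.items():
        lines.append(f"  {cat:28s} {n:5d}")
    if report.rescue_candidates:
        lines += [
            "",
            f"cis-rescue candidates: {len(report.rescue_candidates)} "
            f"({report.n_interesting_rescues} interesting)",
        ]
    if report.triage.get("stages"):
        lines += ["", "triage cascade:"]
        for s in report.triage["stages"]:
            lines.append(
                f"  {s['stage']:24s} {s['variants']:4d} variants "
                f"{s['carriers']:4d} carriers"
            )
    if report.sqtl_top_hit:
        h = report.sqtl_top_hit
        lines += [
            "",
            f"sQTL hits: {report.sqtl_n_hits} "
            f"(top: {h['exon_id']} ~ {h['variant_id']}, q={h['q']:.2e})",
            f"pLoF variants in sQTL exons: {len(report.sqtl_flags)}",
        ]
    if report.recovery:
        lines += [
            "",
            f"truth-table recovery: {report.recovery['n_matched']}"
            f"/{report.recovery['n_checked']}"
            f" ({report.recovery['recovery_pct']}%)",
        ]
    return "\n".join(lines) + "\n"
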