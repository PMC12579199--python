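"""Pipeline configuration: every named threshold, surfaced in one place.

Thresholds default to the values used throughout the analysis (fraction of
protein removed, pext reduction cut-offs, SpliceAI delta-score cut-offs,
allele-balance bands, homopolymer run length, frame-restore pairing window,
candidate-selection caps). All of them can be overridden from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    """Rule-engine and filter thresholds.

    protein_removed_max : float
        A premature stop escaping NMD only counts as a rescue when it removes
        less than this fraction of the protein ("last exon 25").
    pext_rescue_max : float
        Relative pext (exon mean / gene max) at or below this fires the
        low-pext rescue (an ~80% reduction in expression of the region).
    pext_uncertain_max : float
        Relative pext in (pext_rescue_max, pext_uncertain_max] marks the
        variant uncertain (a ~50% reduction).
    splice_gain_min, splice_loss_min : float
        SpliceAI delta-score cut-offs for gained/lost splice sites.
    ab_somatic_max : float
        Median heterozygous allele balance strictly below this suggests a
        somatic variant at curation ("AB below 25").
    ab_triage_max : float
        Allele-balance band (strict <) used by the post-curation triage
        ("under 35%"); values below ab_somatic_max were already consumed
        by the curation rule and below qc_ab_min by genotype QC.
    homopolymer_run_min : int
        Minimum adjacent identical-base run for the homopolymer artifact rule.
    frame_restore_window_bp : int
        Maximum distance between paired frame-restoring indels (same exon).
    qc_dp_min, qc_gq_min, qc_ab_min : genotype QC failure boundaries
        (fail iff dp < qc_dp_min, gq < qc_gq_min, het AB < qc_ab_min).
    plp_ac_max, plp_pli_max, modifier_af_max :
        Candidate selection for the cis-rescue scan (P/LP with AC <= 50 in a
        LoF-tolerant gene, modifiers at global AF <= 1%).
    cooccurrence_min : float
        Strict lower bound on the co-carrier fraction for criterion 1.
    sqtl_fdr, sqtl_window_bp : sQTL association FDR level and cis window.
    """

    protein_removed_max: float = 0.25
    nmd_penultimate_bp: int = 50
    pext_rescue_max: float = 0.2
    pext_uncertain_max: float = 0.5
    splice_gain_min: float = 0.2
    splice_loss_min: float = 0.2
    ab_somatic_max: float = 0.25
    ab_triage_max: float = 0.35
    homopolymer_run_min: int = 6
    frame_restore_window_bp: int = 105
    qc_dp_min: int = 10
    qc_gq_min: int = 20
    qc_ab_min: float = 0.2
    plp_ac_max: int = 50
    plp_pli_max: float = 0.9
    modifier_af_max: float = 0.01
    cooccurrence_min: float = 0.5
    sqtl_fdr: float = 0.05
    sqtl_window_bp: int = 1_000_000


# Verdict strength of each rule when it fires.  The catalog's per-rule
# strengths are configuration rather than code so that a different
# conservative/lenient split can be applied without touching the engine.
DEFAULT_RULE_STRENGTHS: dict[str, str] = {
    "nmd_escape": "not_lof_strong",
    "mnv_rescue": "not_lof_strong",
    "frame_restoring_indel": "not_lof_strong",
    "splice_rescue_strong": "not_lof_strong",
    "splice_rescue_weak": "not_lof_weak",
    "low_pext": "not_lof_weak",
    "somatic_ab": "not_lof_weak",
    "isoform_rescue": "not_lof_weak",
    "homopolymer_artifact": "artifact_uncertain",
}


@dataclass
class PipelineConfig:
    """Full run configuration: thresholds plus cohort-level settings."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    excluded_project: str = "cell_line_cohort"
    seed: int = 0
    out_dir: str = "ptriage_out"

    def to_dict(self) -> dict:
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "excluded_project": self.excluded_project,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        thr = Thresholds(**d.get("thresholds", {}))
        return cls(
            thresholds=thr,
            excluded_project=d.get("excluded_project", "cell_line_cohort"),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir", "ptriage_out"),
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
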