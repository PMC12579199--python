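"""Loss-of-function evasion rule engine.

Every LOFTEE high-confidence pLoF variant (nonsense, frameshift, essential
splice) is evaluated against a catalog of evasion rules — mechanisms by which
a variant annotated as pLoF does not in fact ablate the protein product:
escape from nonsense-mediated decay, low expression of the affected region
(pext), rescue by same-codon multi-nucleotide variants or frame-restoring
indel pairs, splice-prediction rescues, transcript-isoform rescues, somatic
origin suggested by low allele balance, and homopolymer sequencing artifacts.

Rule firings aggregate to a five-level verdict (LoF, Likely LoF, Uncertain
LoF, Likely not LoF, Not LoF) and the verdict maps onto the outcome groups
used downstream: explained / uncertain / unexplained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from .config import DEFAULT_RULE_STRENGTHS, Thresholds
from .genes import STOP_CODONS, TranscriptModel, reverse_complement
from .variants import (
    GenotypeCall,
    PextTrack,
    SpliceAnnotation,
    TranscriptConsequence,
    VariantRecord,
)

VERDICTS = ("LoF", "Likely_LoF", "Uncertain_LoF", "Likely_not_LoF", "Not_LoF")
STRENGTH_RANK = {  # higher rank = further from LoF
    "artifact_uncertain": 1,
    "uncertain": 1,
    "not_lof_weak": 2,
    "not_lof_strong": 3,
}


@dataclass
class RuleResult:
    rule_id: str
    fired: bool
    strength: str | None = None  # not_lof_strong | not_lof_weak | uncertain |
    #                              artifact_uncertain
    category: str | None = None
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.fired and self.category is None:
            raise ValueError(f"fired rule {self.rule_id} without a category")
        if not self.fired:
            self.category = None


@dataclass
class CurationResult:
    variant_id: str
    transcript_id: str | None
    rules: list[RuleResult] = field(default_factory=list)
    verdict: str = "LoF"
    outcome: str = "unexplained"
    category: str | None = None

    def fired(self) -> list[RuleResult]:
        return [r for r in self.rules if r.fired]


def is_hc_plof(variant: VariantRecord) -> bool:
    return variant.loftee == "HC" and any(c.is_plof for c in variant.consequences)


# ---------------------------------------------------------------------------
# Individual rules


def fraction_cds_removed(cds_offset: int, tx: TranscriptModel) -> float:
    """Fraction of the coding sequence 3' of (and including) the variant.

    For a stop-gain or frameshift at CDS offset *o* in a CDS of length *L*
    this is (L - o + 1) / L.
    """
    if not tx.coding:
        raise ValueError(f"{tx.transcript_id} is non-coding")
    length = tx.cds_length
    if not 1 <= cds_offset <= length:
        raise ValueError(f"CDS offset {cds_offset} outside 1..{length}")
    return (length - cds_offset + 1) / length


def rule_nmd_escape(
    csq: TranscriptConsequence, tx: TranscriptModel, thr: Thresholds
) -> RuleResult:
    """Premature stop in the last coding exon or the final coding bp of the
    penultimate exon: the transcript escapes nonsense-mediated decay.  Counts
    as a rescue only when less than 25% of the protein is removed."""
    rid = "nmd_escape"
    if csq.consequence not in ("nonsense", "frameshift") or csq.cds_offset is None:
        return RuleResult(rid, False, evidence="not applicable")
    n_coding = len(tx.coding_exons())
    idx = tx.coding_exon_index(csq.cds_offset)
    in_last = idx == n_coding - 1
    in_penultimate_tail = (
        n_coding >= 2
        and idx == n_coding - 2
        and tx.distance_to_exon_3prime_junction(csq.cds_offset)
        <= thr.nmd_penultimate_bp
    )
    frac = fraction_cds_removed(csq.cds_offset, tx)
    if (in_last or in_penultimate_tail) and frac < thr.protein_removed_max:
        where = "last exon" if in_last else "penultimate exon 3' end"
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "last_exon_25",
            f"{where}; {frac:.1%} of CDS removed",
        )
    return RuleResult(rid, False, evidence=f"{frac:.1%} removed, exon {idx + 1}")


def rule_low_pext(
    variant: VariantRecord, track: PextTrack | None, thr: Thresholds
) -> RuleResult:
    """Variant region expressed in a minor fraction of transcripts: relative
    pext <= 20% of the gene maximum rescues; <= 50% is uncertain."""
    rid = "low_pext"
    r = None if track is None else track.relative_score_at(variant.pos)
    if r is None:
        return RuleResult(rid, False, evidence="no data")
    eps = 1e-9  # boundary-inclusive thresholds, robust to float division
    if r <= thr.pext_rescue_max + eps:
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "low_pext",
            f"relative pext {r:.2f} (>= {1 - r:.0%} reduction)",
        )
    if r <= thr.pext_uncertain_max + eps:
        return RuleResult(
            rid, True, "uncertain", "low_pext",
            f"relative pext {r:.2f} ({1 - r:.0%} reduction)",
        )
    return RuleResult(rid, False, evidence=f"relative pext {r:.2f}")


def _apply_cds_snv(
    codon: str, within: int, genomic_alt: str, strand: str
) -> str:
    base = genomic_alt if strand == "+" else reverse_complement(genomic_alt)
    return codon[:within] + base + codon[within + 1 :]


def rule_mnv_rescue(
    variant: VariantRecord,
    csq: TranscriptConsequence,
    tx: TranscriptModel,
    contig_seq: str,
    carrier_other_variants: dict[str, list[tuple[VariantRecord, TranscriptConsequence]]],
    thr: Thresholds,
) -> RuleResult:
    """Same-codon partner SNV turns the apparent stop codon into a
    non-stop codon (a multi-nucleotide variant).  The rescue requires the
    partner in every carrier; mixed per-carrier evidence is uncertain."""
    rid = "mnv_rescue"
    if csq.consequence != "nonsense" or not variant.is_snv or csq.cds_offset is None:
        return RuleResult(rid, False, evidence="not applicable")
    ref_base = contig_seq[variant.pos - 1].upper()
    if ref_base != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.variant_id}: FASTA has {ref_base}"
        )
    if not carrier_other_variants:
        return RuleResult(rid, False, evidence="no carriers")
    codon_index = (csq.cds_offset - 1) // 3
    ref_codon = tx.codon_at(contig_seq, codon_index)
    mutated = _apply_cds_snv(
        ref_codon, (csq.cds_offset - 1) % 3, variant.alt, tx.strand
    )
    if mutated not in STOP_CODONS:
        return RuleResult(rid, False, evidence="variant does not create a stop")
    rescued = 0
    for sample, others in carrier_other_variants.items():
        ok = False
        for other, ocsq in others:
            if not other.is_snv or ocsq.cds_offset is None:
                continue
            if (ocsq.cds_offset - 1) // 3 != codon_index:
                continue
            joint = _apply_cds_snv(
                mutated, (ocsq.cds_offset - 1) % 3, other.alt, tx.strand
            )
            if joint not in STOP_CODONS:
                ok = True
                break
        rescued += ok
    n = len(carrier_other_variants)
    if rescued == n:
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "mnv",
            f"rescuing same-codon partner in {n}/{n} carriers",
        )
    if rescued > 0:
        return RuleResult(
            rid, True, "uncertain", "mnv",
            f"rescuing partner in only {rescued}/{n} carriers",
        )
    return RuleResult(rid, False, evidence=f"no same-codon partner (0/{n})")


def _indel_signed_length(v: VariantRecord) -> int:
    return len(v.alt) - len(v.ref)


def _shifted_frame_stop_free(
    cds_seq: str,
    off5: int,
    var5: VariantRecord,
    off3: int,
    strand: str,
) -> bool:
    """No stop codon in the out-of-frame segment between two indels.

    The 5'-most indel (in CDS orientation) is applied to the CDS, then
    codons are scanned in the shifted frame from the first indel up to the
    restoring indel."""
    slen = _indel_signed_length(var5)
    if slen < 0:
        d = -slen
        shifted = cds_seq[: off5 - 1] + cds_seq[off5 - 1 + d :]
        start = off5 - 1
        idx3 = off3 - 1 - d
    else:
        ins = var5.alt[len(var5.ref) :]
        if strand == "-":
            ins = reverse_complement(ins)
        shifted = cds_seq[:off5] + ins + cds_seq[off5:]
        start = off5
        idx3 = off3 - 1 + slen
    seg = shifted[start : idx3 + 1]
    return all(
        seg[i : i + 3] not in STOP_CODONS for i in range(0, len(seg) - 2, 3)
    )


def rule_frame_restoring_indel(
    variant: VariantRecord,
    csq: TranscriptConsequence,
    tx: TranscriptModel,
    contig_seq: str,
    carrier_other_variants: dict[str, list[tuple[VariantRecord, TranscriptConsequence]]],
    thr: Thresholds,
) -> RuleResult:
    """A second nearby indel restores the reading frame: signed lengths sum
    to 0 mod 3, both in the same exon within the pairing window, and the
    intervening out-of-frame stretch introduces no stop codon."""
    rid = "frame_restoring_indel"
    slen = _indel_signed_length(variant)
    if csq.consequence != "frameshift" or slen % 3 == 0 or csq.cds_offset is None:
        return RuleResult(rid, False, evidence="not applicable")
    if not carrier_other_variants:
        return RuleResult(rid, False, evidence="no carriers")
    cds_seq = tx.cds_sequence(contig_seq)
    my_exon = tx.exon_containing(variant.pos)
    rescued = 0
    for sample, others in carrier_other_variants.items():
        ok = False
        for other, ocsq in others:
            olen = _indel_signed_length(other)
            if olen == 0 or ocsq.cds_offset is None:
                continue
            if (slen + olen) % 3 != 0:
                continue
            if abs(ocsq.cds_offset - csq.cds_offset) > thr.frame_restore_window_bp:
                continue
            if tx.exon_containing(other.pos) != my_exon:
                continue
            if csq.cds_offset <= ocsq.cds_offset:
                off5, v5, off3 = csq.cds_offset, variant, ocsq.cds_offset
            else:
                off5, v5, off3 = ocsq.cds_offset, other, csq.cds_offset
            if _shifted_frame_stop_free(cds_seq, off5, v5, off3, tx.strand):
                ok = True
                break
        rescued += ok
    n = len(carrier_other_variants)
    if rescued == n:
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "frame_restore",
            f"frame-restoring partner in {n}/{n} carriers",
        )
    if rescued > 0:
        return RuleResult(
            rid, True, "uncertain", "frame_restore",
            f"restoring partner in only {rescued}/{n} carriers",
        )
    return RuleResult(rid, False, evidence=f"no restoring partner (0/{n})")


def rule_somatic_ab(
    carrier_calls: list[GenotypeCall], thr: Thresholds
) -> RuleResult:
    """Median allele balance of heterozygous carriers below 25% suggests the
    variant is somatic rather than germline."""
    rid = "somatic_ab"
    abs_ = [
        ab
        for c in carrier_calls
        if c.gt == "het" and (ab := c.allele_balance()) is not None
    ]
    if not abs_:
        return RuleResult(rid, False, evidence="no data")
    med = median(abs_)
    if med < thr.ab_somatic_max:
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "ab_below_25",
            f"median het AB {med:.3f} over {len(abs_)} carriers",
        )
    return RuleResult(rid, False, evidence=f"median het AB {med:.3f}")


def rule_splice_rescue(
    variant: VariantRecord,
    annot: SpliceAnnotation | None,
    tx: TranscriptModel,
    thr: Thresholds,
) -> RuleResult:
    """Splice-prediction rescues for essential splice variants, first match
    wins: (a) in-frame skip of a small adjacent exon, (b) in-frame
    alternative splice site, (c) no splice loss predicted at all."""
    rid = "splice_rescue"
    if annot is None:
        return RuleResult(rid, False, evidence="no data")
    cds_len = tx.cds_length
    adj = tx.adjacent_exon_for_splice(variant.pos)
    if adj is not None and annot.max_loss >= thr.splice_loss_min:
        exon_cds = tx.exon_coding_length(adj)
        if exon_cds > 0 and exon_cds % 3 == 0 and exon_cds / cds_len < thr.protein_removed_max:
            return RuleResult(
                rid, True, DEFAULT_RULE_STRENGTHS["splice_rescue_strong"],
                "inframe_exon_skip_25",
                f"in-frame skip of {exon_cds} bp exon "
                f"({exon_cds / cds_len:.1%} of CDS)",
            )
    for score, offset, site in (
        (annot.donor_gain, annot.donor_gain_pos, "donor"),
        (annot.acceptor_gain, annot.acceptor_gain_pos, "acceptor"),
    ):
        if (
            score >= thr.splice_gain_min
            and offset != 0
            and offset % 3 == 0
            and abs(offset) / cds_len < thr.protein_removed_max
        ):
            return RuleResult(
                rid, True, DEFAULT_RULE_STRENGTHS["splice_rescue_strong"],
                "inframe_alt_site",
                f"in-frame alternative {site} site at {offset:+d} bp "
                f"(delta {score:.2f})",
            )
    if (
        annot.acceptor_loss < thr.splice_loss_min
        and annot.donor_loss < thr.splice_loss_min
    ):
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS["splice_rescue_weak"],
            "no_loss_detected",
            f"max loss delta {annot.max_loss:.2f} < {thr.splice_loss_min}",
        )
    return RuleResult(rid, False, evidence="splice loss predicted, no rescue")


def rule_isoform_rescue(
    variant: VariantRecord,
    csq: TranscriptConsequence,
    tx: TranscriptModel,
    gene_transcripts: list[TranscriptModel],
    thr: Thresholds,
) -> RuleResult:
    """Transcript-isoform rescues: the variant's exon belongs only to a
    likely-non-coding isoform; or an annotated in-frame downstream start in
    the first coding exon re-initiates translation; or the exon is an
    overhang unique to a non-reference isoform."""
    rid = "isoform_rescue"
    pos = variant.pos

    def _has_exon(t: TranscriptModel) -> bool:
        return t.exon_containing(pos) is not None

    relevant_coding = [
        t for t in gene_transcripts
        if t.mane_select or (t.coding and not t.noncoding_likely)
    ]
    noncoding_like = [t for t in gene_transcripts if t.noncoding_likely]
    if (
        noncoding_like
        and not any(_has_exon(t) for t in relevant_coding)
        and any(_has_exon(t) for t in noncoding_like)
    ):
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "noncoding_isoform",
            "exon present only in likely-non-coding isoforms",
        )
    if (
        tx.alt_start_cds_offset is not None
        and csq.consequence in ("nonsense", "frameshift")
        and csq.cds_offset is not None
        and csq.cds_offset < tx.alt_start_cds_offset
        and tx.coding_exon_index(csq.cds_offset) == 0
        and tx.coding_exon_index(tx.alt_start_cds_offset) == 0
        and (tx.alt_start_cds_offset - 1) % 3 == 0
        and (tx.alt_start_cds_offset - 1) / tx.cds_length < thr.protein_removed_max
    ):
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "downstream_met",
            f"in-frame downstream start at CDS offset {tx.alt_start_cds_offset}",
        )
    mane = [t for t in gene_transcripts if t.mane_select]
    if mane and not any(_has_exon(t) for t in mane):
        overhang = [
            t for t in gene_transcripts
            if not t.mane_select and not t.noncoding_likely and t.coding
            and _has_exon(t)
        ]
        if overhang:
            return RuleResult(
                rid, True, DEFAULT_RULE_STRENGTHS[rid], "overhang_exon",
                f"exon unique to non-reference isoform {overhang[0].transcript_id}",
            )
    return RuleResult(rid, False, evidence="exon shared with reference isoform")


def rule_homopolymer_artifact(
    variant: VariantRecord, contig_seq: str, thr: Thresholds
) -> RuleResult:
    """Indel whose inserted/deleted unit matches an adjacent reference run of
    identical bases: a likely sequencing artifact."""
    rid = "homopolymer_artifact"
    if not variant.is_indel:
        return RuleResult(rid, False, evidence="not an indel")
    if len(variant.ref) > len(variant.alt):
        unit = variant.ref[len(variant.alt) :]
    else:
        unit = variant.alt[len(variant.ref) :]
    if not unit or any(b != unit[0] for b in unit):
        return RuleResult(rid, False, evidence="indel unit not a homopolymer")
    base = unit[0].upper()
    # maximal run of `base` in the reference starting right of the anchor
    i = variant.pos  # 0-based index of the base after the anchor position
    run = 0
    while i < len(contig_seq) and contig_seq[i].upper() == base:
        run += 1
        i += 1
    # extend left of the anchor as well
    i = variant.pos - 2
    while i >= 0 and contig_seq[i].upper() == base:
        run += 1
        i -= 1
    if run >= thr.homopolymer_run_min:
        return RuleResult(
            rid, True, DEFAULT_RULE_STRENGTHS[rid], "homopolymer",
            f"{base}-run of {run} adjacent to indel",
        )
    return RuleResult(rid, False, evidence=f"adjacent run {run} < {thr.homopolymer_run_min}")


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_verdict(results: list[RuleResult]) -> str:
    """Fold rule firings into the five-level verdict.

    Any strong not-LoF rescue dominates; weak rescues give Likely not LoF;
    uncertain or artifact evidence alone gives Uncertain LoF; with no firing
    at all the variant remains LoF.
    """
    fired = [r for r in results if r.fired]
    strengths = {r.strength for r in fired}
    if "not_lof_strong" in strengths:
        return "Not_LoF"
    if "not_lof_weak" in strengths:
        return "Likely_not_LoF"
    if "uncertain" in strengths or "artifact_uncertain" in strengths:
        return "Uncertain_LoF"
    return "LoF"


def aggregate_category(results: list[RuleResult], verdict: str) -> str | None:
    if verdict not in ("Not_LoF", "Likely_not_LoF"):
        return None
    cats = sorted(
        {
            r.category
            for r in results
            if r.fired and r.strength in ("not_lof_strong", "not_lof_weak")
        }
    )
    if len(cats) >= 2:
        return "combination_of_explanations"
    return cats[0] if cats else None


def classify_outcome(verdict: str) -> str:
    if verdict not in VERDICTS:
        raise ValueError(f"unknown verdict {verdict!r}")
    if verdict in ("Not_LoF", "Likely_not_LoF"):
        return "explained"
    if verdict == "Uncertain_LoF":
        return "uncertain"
    return "unexplained"


# ---------------------------------------------------------------------------
# Engine


class CurationEngine:
    """Evaluates the rule catalog over a cohort.

    Curation is performed per MANE Select transcript when the variant has a
    consequence there, else on the longest coding transcript among those
    with consequences; the chosen transcript is recorded in the result.
    """

    def __init__(
        self,
        transcripts: dict[str, TranscriptModel],
        reference: dict[str, str],
        pext: dict[str, PextTrack],
        splice: dict[str, SpliceAnnotation],
        genotypes: dict[str, dict[str, GenotypeCall]],
        variants: list[VariantRecord],
        thresholds: Thresholds | None = None,
    ):
        self.transcripts = transcripts
        self.reference = reference
        self.pext = pext
        self.splice = splice
        self.genotypes = genotypes
        self.thresholds = thresholds or Thresholds()
        self.variants_by_id = {v.variant_id: v for v in variants}
        # sample -> variant_ids carried (for partner-variant lookups)
        self._carried: dict[str, set[str]] = {}
        for vid, calls in genotypes.items():
            for sid, call in calls.items():
                if call.is_carrier:
                    self._carried.setdefault(sid, set()).add(vid)

    # -- helpers -----------------------------------------------------------

    def choose_transcript(
        self, variant: VariantRecord
    ) -> tuple[TranscriptModel | None, TranscriptConsequence | None]:
        candidates = [
            (self.transcripts[c.transcript_id], c)
            for c in variant.consequences
            if c.transcript_id in self.transcripts
        ]
        if not candidates:
            return None, None
        for t, c in candidates:
            if t.mane_select:
                return t, c
        coding = [(t, c) for t, c in candidates if t.coding]
        if coding:
            return max(coding, key=lambda tc: tc[0].cds_length)
        return candidates[0]

    def carriers_of(self, variant_id: str) -> list[GenotypeCall]:
        return [
            c for c in self.genotypes.get(variant_id, {}).values() if c.is_carrier
        ]

    def _carrier_partners(
        self, variant: VariantRecord, tx: TranscriptModel
    ) -> dict[str, list[tuple[VariantRecord, TranscriptConsequence]]]:
        """Per carrier: the other variants they carry with a consequence on
        the curated transcript."""
        out: dict[str, list] = {}
        for call in self.carriers_of(variant.variant_id):
            others = []
            for vid in self._carried.get(call.sample_id, ()):
                if vid == variant.variant_id:
                    continue
                other = self.variants_by_id.get(vid)
                if other is None:
                    continue
                ocsq = other.consequence_on(tx.transcript_id)
                if ocsq is not None:
                    others.append((other, ocsq))
            out[call.sample_id] = others
        return out

    # -- main entry points ---------------------------------------------------

    def curate(self, variant: VariantRecord) -> CurationResult:
        thr = self.thresholds
        tx, csq = self.choose_transcript(variant)
        if tx is None or csq is None:
            res = CurationResult(variant.variant_id, None)
            res.verdict = "Uncertain_LoF"
            res.outcome = classify_outcome(res.verdict)
            return res
        contig_seq = self.reference.get(tx.contig, "")
        partners = self._carrier_partners(variant, tx)
        carrier_calls = self.carriers_of(variant.variant_id)
        track = self.pext.get(csq.gene)
        gene_txs = [t for t in self.transcripts.values() if t.gene == csq.gene]

        rules = [
            rule_nmd_escape(csq, tx, thr) if tx.coding
            else RuleResult("nmd_escape", False, evidence="non-coding transcript"),
            rule_low_pext(variant, track, thr),
            rule_mnv_rescue(variant, csq, tx, contig_seq, partners, thr)
            if tx.coding and contig_seq
            else RuleResult("mnv_rescue", False, evidence="no reference"),
            rule_frame_restoring_indel(variant, csq, tx, contig_seq, partners, thr)
            if tx.coding and contig_seq
            else RuleResult("frame_restoring_indel", False, evidence="no reference"),
            rule_somatic_ab(carrier_calls, thr),
            rule_splice_rescue(variant, self.splice.get(variant.variant_id), tx, thr)
            if csq.consequence == "essential_splice"
            else RuleResult("splice_rescue", False, evidence="not a splice variant"),
            rule_isoform_rescue(variant, csq, tx, gene_txs, thr),
            rule_homopolymer_artifact(variant, contig_seq, thr)
            if contig_seq
            else RuleResult("homopolymer_artifact", False, evidence="no reference"),
        ]
        verdict = aggregate_verdict(rules)
        return CurationResult(
            variant_id=variant.variant_id,
            transcript_id=tx.transcript_id,
            rules=rules,
            verdict=verdict,
            outcome=classify_outcome(verdict),
            category=aggregate_category(rules, verdict),
        )

    def curate_all(
        self, variants: list[VariantRecord] | None = None
    ) -> dict[str, CurationResult]:
        pool = variants if variants is not None else list(self.variants_by_id.values())
        return {
            v.variant_id: self.curate(v) for v in pool if is_hc_plof(v)
        }


def outcome_tallies(results: dict[str, CurationResult]) -> dict[str, int]:
    tally = {"explained": 0, "uncertain": 0, "unexplained": 0}
    for r in results.values():
        tally[r.outcome] += 1
    return tally


def category_frequency_table(results: dict[str, CurationResult]) -> dict[str, int]:
    """Counts of explanation categories among explained variants, the
    ranked-table analog of the per-category evasion breakdown."""
    counts: dict[str, int] = {}
    for r in results.values():
        if r.outcome == "explained" and r.category:
            counts[r.category] = counts.get(r.category, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
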