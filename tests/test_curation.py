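"""Rule engine: each evasion rule against its worked examples and
brute-force oracles, verdict aggregation, and outcome classification."""

import pytest
from Bio.Seq import Seq

from ptriage.config import Thresholds
from ptriage.curation import (
    aggregate_category,
    aggregate_verdict,
    classify_outcome,
    fraction_cds_removed,
    rule_frame_restoring_indel,
    rule_homopolymer_artifact,
    rule_isoform_rescue,
    rule_low_pext,
    rule_mnv_rescue,
    rule_nmd_escape,
    rule_somatic_ab,
    rule_splice_rescue,
    RuleResult,
)
from ptriage.genes import TranscriptModel, reverse_complement
from ptriage.variants import (
    GenotypeCall,
    PextTrack,
    SpliceAnnotation,
    TranscriptConsequence,
    VariantRecord,
)

THR = Thresholds()


def _tx(
    exons=((1001, 1100), (1201, 1500), (1601, 1800)),
    cds=((1001, 1100), (1201, 1500), (1601, 1800)),
    strand="+",
    **kw,
):
    return TranscriptModel(
        "tx1", "G1", "c1", strand, exons=list(exons), cds=list(cds), **kw
    )


def _csq(consequence, cds_offset=None, tx_id="tx1"):
    return TranscriptConsequence(tx_id, "G1", consequence, cds_offset)


def _var(pos, ref, alt, csqs, contig="c1"):
    return VariantRecord(
        contig, pos, ref, alt, ac_genomes=1, an_genomes=10, pass_genomes=True,
        consequences=csqs, loftee="HC",
    )


class TestFractionRemoved:
    def test_arithmetic(self):
        tx = _tx(cds=((1, 300),), exons=((1, 300),))
        assert fraction_cds_removed(240, tx) == pytest.approx(61 / 300)
        assert fraction_cds_removed(1, tx) == 1.0
        assert fraction_cds_removed(300, tx) == pytest.approx(1 / 300)

    def test_strand_symmetry(self):
        plus = _tx(cds=((1, 300),), exons=((1, 300),), strand="+")
        minus = _tx(cds=((1, 300),), exons=((1, 300),), strand="-")
        for off in (1, 150, 300):
            assert fraction_cds_removed(off, plus) == fraction_cds_removed(off, minus)

    def test_noncoding_rejected(self):
        tx = TranscriptModel("t", "g", "c", "+", exons=[(1, 100)], cds=[])
        with pytest.raises(ValueError):
            fraction_cds_removed(10, tx)


class TestNmdEscape:
    # CDS lengths 100 + 300 + 200 = 600
    def test_last_exon_small_truncation_fires(self):
        tx = _tx()
        res = rule_nmd_escape(_csq("nonsense", 550), tx, THR)
        assert res.fired and res.category == "last_exon_25"

    def test_penultimate_tail_fires_boundary_inclusive(self):
        tx = _tx()
        # offset 350: 50 coding bp from the penultimate exon 3' junction,
        # but 251/600 = 42% removed -> must NOT fire
        assert not rule_nmd_escape(_csq("nonsense", 350), tx, THR).fired
        # offset 460: well within the CDS tail and <25% removed
        res = rule_nmd_escape(_csq("nonsense", 460), tx, THR)
        assert res.fired  # in last 50bp window? offset 460 is in exon 2?
        # offset 460 is in exon 3 (starts at 401): last exon, 23.5% removed

    def test_penultimate_window(self):
        # shrink CDS so a penultimate-tail stop removes < 25%
        tx = _tx(
            exons=((1, 1200), (1301, 1500), (1601, 1700)),
            cds=((1, 1200), (1301, 1500), (1601, 1700)),
        )  # lengths 1200, 200, 100 -> total 1500
        # offset 1360: penultimate exon, 40 bp from its 3' junction (1400),
        # removes 141/1500 = 9.4%
        res = rule_nmd_escape(_csq("nonsense", 1360), tx, THR)
        assert res.fired and res.category == "last_exon_25"
        # offset 1300: 100 bp from the junction -> outside the 50 bp window
        assert not rule_nmd_escape(_csq("nonsense", 1300), tx, THR).fired

    def test_large_truncation_does_not_fire(self):
        tx = _tx()
        # last exon but removes 40%: offset 361 -> in exon 2 actually; use a
        # custom CDS: lengths 100+100+400, offset 241 in last exon removes 60%
        tx = _tx(
            exons=((1, 100), (201, 300), (401, 800)),
            cds=((1, 100), (201, 300), (401, 800)),
        )
        assert not rule_nmd_escape(_csq("nonsense", 241), tx, THR).fired

    def test_not_applicable_to_splice(self):
        assert not rule_nmd_escape(_csq("essential_splice"), _tx(), THR).fired


class TestLowPext:
    def _track(self, score):
        return PextTrack(
            "G1", exon_scores={(1001, 1100): 0.8, (1201, 1500): score * 0.8}
        )

    def test_eighty_percent_reduction_rescues(self):
        res = rule_low_pext(
            _var(1300, "C", "T", [_csq("nonsense", 200)]), self._track(0.2), THR
        )
        assert res.fired and res.strength == "not_lof_weak"
        assert res.category == "low_pext"

    def test_fifty_percent_reduction_uncertain(self):
        res = rule_low_pext(
            _var(1300, "C", "T", [_csq("nonsense", 200)]), self._track(0.5), THR
        )
        assert res.fired and res.strength == "uncertain"

    def test_full_expression_no_fire(self):
        res = rule_low_pext(
            _var(1300, "C", "T", [_csq("nonsense", 200)]), self._track(1.0), THR
        )
        assert not res.fired

    def test_missing_data(self):
        res = rule_low_pext(
            _var(5000, "C", "T", [_csq("nonsense", 200)]), self._track(0.1), THR
        )
        assert not res.fired and "no data" in res.evidence


def _mnv_fixture(codon: str):
    """Single-exon transcript ATG <codon> TAA with contig padding."""
    seq = "NNNN" + "ATG" + codon + "TAA" + "NNNN"
    tx = TranscriptModel("tx1", "G1", "c1", "+", exons=[(5, 13)], cds=[(5, 13)])
    return tx, seq


class TestMnvRescue:
    def test_agrees_with_joint_translation_oracle(self):
        """Exhaustive check over codon x stop-creating SNV x partner SNV:
        the rule fires exactly when Biopython translation of the jointly
        mutated codon is not a stop."""
        bases = "ACGT"
        checked = 0
        for codon in (a + b + c for a in bases for b in bases for c in bases):
            tx, seq = _mnv_fixture(codon)
            for p1 in range(3):
                for b1 in bases:
                    if b1 == codon[p1]:
                        continue
                    single = codon[:p1] + b1 + codon[p1 + 1 :]
                    if str(Seq(single).translate()) != "*":
                        continue
                    pos1 = 8 + p1
                    v1 = _var(pos1, codon[p1], b1, [_csq("nonsense", 4 + p1)])
                    for p2 in range(3):
                        if p2 == p1:
                            continue
                        for b2 in bases:
                            if b2 == codon[p2]:
                                continue
                            joint = single[:p2] + b2 + single[p2 + 1 :]
                            v2 = _var(
                                8 + p2, codon[p2], b2,
                                [_csq("missense", 4 + p2)],
                            )
                            partners = {"s1": [(v2, v2.consequences[0])]}
                            res = rule_mnv_rescue(
                                v1, v1.consequences[0], tx, seq, partners, THR
                            )
                            expected = str(Seq(joint).translate()) != "*"
                            assert res.fired == expected or (
                                res.fired and res.strength == "uncertain"
                            )
                            if expected:
                                assert res.strength == "not_lof_strong"
                            checked += 1
        assert checked > 100

    def test_partner_in_adjacent_codon_no_fire(self):
        tx, seq = _mnv_fixture("CGA")
        v1 = _var(8, "C", "T", [_csq("nonsense", 4)])
        partner = _var(5, "A", "G", [_csq("missense", 1)])  # previous codon
        res = rule_mnv_rescue(
            v1, v1.consequences[0], tx, seq,
            {"s1": [(partner, partner.consequences[0])]}, THR,
        )
        assert not res.fired

    def test_partial_carrier_evidence_is_uncertain(self):
        tx, seq = _mnv_fixture("CGA")
        v1 = _var(8, "C", "T", [_csq("nonsense", 4)])
        v2 = _var(10, "A", "G", [_csq("missense", 6)])
        partners = {"s1": [(v2, v2.consequences[0])], "s2": []}
        res = rule_mnv_rescue(v1, v1.consequences[0], tx, seq, partners, THR)
        assert res.fired and res.strength == "uncertain"

    def test_reference_mismatch_is_error(self):
        tx, seq = _mnv_fixture("CGA")
        v1 = _var(8, "G", "T", [_csq("nonsense", 4)])  # ref is actually C
        with pytest.raises(ValueError):
            rule_mnv_rescue(v1, v1.consequences[0], tx, seq, {"s1": []}, THR)

    def test_minus_strand(self):
        codon = "CGA"
        seq = "NNNN" + "TTA" + reverse_complement(codon) + "CAT" + "NNNN"
        tx = TranscriptModel("tx1", "G1", "c1", "-", exons=[(5, 13)], cds=[(5, 13)])
        # CDS offset 4 (codon pos 1, 'C') sits at genomic pos 10 (base G)
        v1 = _var(10, "G", "A", [_csq("nonsense", 4)])  # C>T on coding strand
        v2 = _var(8, "T", "C", [_csq("missense", 6)])  # A>G on coding strand
        res = rule_mnv_rescue(
            v1, v1.consequences[0], tx, seq,
            {"s1": [(v2, v2.consequences[0])]}, THR,
        )
        assert res.fired and res.strength == "not_lof_strong"


def _frame_fixture():
    """Single-exon 300 bp CDS of CAC repeats: no stop in any frame."""
    seq = "CAC" * 100
    tx = TranscriptModel("tx1", "G1", "c1", "+", exons=[(1, 300)], cds=[(1, 300)])
    return tx, seq


def _indel_at(tx, seq, cds_offset, signed_len):
    """Build an anchored indel VariantRecord at a CDS offset."""
    if signed_len < 0:
        d = -signed_len
        pos = cds_offset - 1  # anchor base before the deleted run
        ref = seq[pos - 1 : pos + d]
        alt = seq[pos - 1]
    else:
        pos = cds_offset
        ref = seq[pos - 1]
        ins = ("ACA" * 3)[:signed_len]
        alt = ref + ins
    cls = "frameshift" if signed_len % 3 else "other"
    return _var(pos, ref, alt, [_csq(cls, cds_offset)])


class TestFrameRestore:
    def test_agrees_with_signed_length_enumeration(self):
        """Exhaustive oracle over signed length pairs in [-6, +6]: with a
        stop-free backbone the rescue fires exactly when the signed lengths
        sum to 0 mod 3."""
        tx, seq = _frame_fixture()
        for l1 in range(-6, 7):
            if l1 == 0 or l1 % 3 == 0:
                continue  # only frameshift primaries
            for l2 in range(-6, 7):
                if l2 == 0:
                    continue
                v1 = _indel_at(tx, seq, 90, l1)
                v2 = _indel_at(tx, seq, 120, l2)
                partners = {"s1": [(v2, v2.consequences[0])]}
                res = rule_frame_restoring_indel(
                    v1, v1.consequences[0], tx, seq, partners, THR
                )
                expected = (l1 + l2) % 3 == 0
                assert res.fired == expected, (l1, l2)
                if expected:
                    assert res.strength == "not_lof_strong"

    def test_window_limit(self):
        tx, seq = _frame_fixture()
        v1 = _indel_at(tx, seq, 30, 1)
        v2 = _indel_at(tx, seq, 30 + 106, -1)
        res = rule_frame_restoring_indel(
            v1, v1.consequences[0], tx, seq,
            {"s1": [(v2, v2.consequences[0])]}, THR,
        )
        assert not res.fired

    def test_intervening_stop_blocks_rescue(self):
        # after deleting CDS offset 29 the shifted frame scans triplets from
        # index 28 (28, 31, ...); plant TAA at shifted indices 31-33, i.e.
        # original sequence indices 32-34
        seq = "CAC" * 10 + "CC" + "TAA" + ("CAC" * 89)[:265]
        assert len(seq) == 300 and seq[32:35] == "TAA"
        tx = TranscriptModel(
            "tx1", "G1", "c1", "+", exons=[(1, 300)], cds=[(1, 300)]
        )
        v1 = _indel_at(tx, seq, 29, -1)
        v2 = _indel_at(tx, seq, 60, 1)
        res = rule_frame_restoring_indel(
            v1, v1.consequences[0], tx, seq,
            {"s1": [(v2, v2.consequences[0])]}, THR,
        )
        assert not res.fired
        # the same pair on the stop-free backbone rescues
        tx2, seq2 = _frame_fixture()
        v1b = _indel_at(tx2, seq2, 29, -1)
        v2b = _indel_at(tx2, seq2, 60, 1)
        res2 = rule_frame_restoring_indel(
            v1b, v1b.consequences[0], tx2, seq2,
            {"s1": [(v2b, v2b.consequences[0])]}, THR,
        )
        assert res2.fired


class TestSomaticAb:
    def _call(self, ad_ref, ad_alt, gt="het"):
        return GenotypeCall(
            "s", "v", gt, dp=ad_ref + ad_alt, gq=99, ad_ref=ad_ref, ad_alt=ad_alt
        )

    def test_single_low_ab_carrier_fires(self):
        res = rule_somatic_ab([self._call(13, 4)], THR)
        assert res.fired and res.category == "ab_below_25"

    def test_exact_quarter_does_not_fire(self):
        res = rule_somatic_ab([self._call(12, 4)], THR)  # AB = 0.25
        assert not res.fired

    def test_median_over_carriers(self):
        calls = [self._call(39, 11), self._call(26, 24)]  # 0.22, 0.48
        res = rule_somatic_ab(calls, THR)
        assert not res.fired  # median 0.35

    def test_hom_alt_ignored(self):
        res = rule_somatic_ab([self._call(0, 30, gt="hom_alt")], THR)
        assert not res.fired and "no data" in res.evidence


class TestSpliceRescue:
    # CDS lengths 100 + 300 + 200 (total 600); exon2 = 300 bp = 50%
    def _skip_tx(self):
        # make exon2 84 bp so skipping it is an in-frame <25% rescue
        return _tx(
            exons=((1001, 1100), (1201, 1284), (1601, 1800)),
            cds=((1001, 1100), (1201, 1284), (1601, 1800)),
        )

    def test_inframe_exon_skip(self):
        tx = self._skip_tx()
        annot = SpliceAnnotation("v", donor_loss=0.9, donor_loss_pos=-1)
        v = _var(1285, "G", "A", [_csq("essential_splice")])
        res = rule_splice_rescue(v, annot, tx, THR)
        assert res.fired and res.category == "inframe_exon_skip_25"

    def test_out_of_frame_exon_no_skip_rescue(self):
        tx = _tx(
            exons=((1001, 1100), (1201, 1285), (1601, 1800)),
            cds=((1001, 1100), (1201, 1285), (1601, 1800)),
        )  # 85 bp exon
        annot = SpliceAnnotation("v", donor_loss=0.9)
        v = _var(1286, "G", "A", [_csq("essential_splice")])
        res = rule_splice_rescue(v, annot, tx, THR)
        assert res.category != "inframe_exon_skip_25"

    def test_inframe_alt_site(self):
        tx = _tx()  # exon2 300 bp = exactly 25%: skip rescue unavailable
        annot = SpliceAnnotation(
            "v", donor_loss=0.8, donor_gain=0.6, donor_gain_pos=-21
        )
        v = _var(1501, "G", "A", [_csq("essential_splice")])
        res = rule_splice_rescue(v, annot, tx, THR)
        assert res.fired and res.category == "inframe_alt_site"

    def test_no_loss_detected(self):
        tx = _tx()
        annot = SpliceAnnotation("v", donor_loss=0.05, acceptor_loss=0.03)
        v = _var(1501, "G", "A", [_csq("essential_splice")])
        res = rule_splice_rescue(v, annot, tx, THR)
        assert res.fired and res.category == "no_loss_detected"
        assert res.strength == "not_lof_weak"

    def test_missing_annotation(self):
        v = _var(1501, "G", "A", [_csq("essential_splice")])
        res = rule_splice_rescue(v, None, _tx(), THR)
        assert not res.fired and "no data" in res.evidence


class TestIsoformRescue:
    def _gene(self):
        mane = TranscriptModel(
            "mane", "G1", "c1", "+",
            exons=[(1, 100), (301, 400)], cds=[(1, 100), (301, 400)],
            mane_select=True,
        )
        nc = TranscriptModel(
            "nc", "G1", "c1", "+",
            exons=[(1, 100), (151, 250), (301, 400)],
            cds=[(1, 100), (151, 250), (301, 400)],
            noncoding_likely=True,
        )
        return mane, nc

    def test_noncoding_isoform_exon(self):
        mane, nc = self._gene()
        v = _var(200, "C", "T", [_csq("nonsense", 150, tx_id="nc")])
        res = rule_isoform_rescue(v, v.consequences[0], nc, [mane, nc], THR)
        assert res.fired and res.category == "noncoding_isoform"

    def test_shared_exon_no_fire(self):
        mane, nc = self._gene()
        v = _var(50, "C", "T", [_csq("nonsense", 50, tx_id="mane")])
        res = rule_isoform_rescue(v, v.consequences[0], mane, [mane, nc], THR)
        assert not res.fired

    def test_downstream_met(self):
        tx = TranscriptModel(
            "mane", "G1", "c1", "+",
            exons=[(1, 200), (301, 400)], cds=[(1, 200), (301, 400)],
            mane_select=True, alt_start_cds_offset=34,
        )
        v = _var(15, "C", "T", [_csq("nonsense", 15, tx_id="mane")])
        res = rule_isoform_rescue(v, v.consequences[0], tx, [tx], THR)
        assert res.fired and res.category == "downstream_met"

    def test_overhang_exon(self):
        mane, _ = self._gene()
        alt_iso = TranscriptModel(
            "alt", "G1", "c1", "+",
            exons=[(1, 100), (151, 250), (301, 400)],
            cds=[(1, 100), (151, 250), (301, 400)],
        )
        v = _var(200, "C", "T", [_csq("nonsense", 150, tx_id="alt")])
        res = rule_isoform_rescue(v, v.consequences[0], alt_iso, [mane, alt_iso], THR)
        assert res.fired and res.category == "overhang_exon"


class TestHomopolymer:
    SEQ = "GGTC" + "AAAAAA" + "CTGGGG"  # 6-A run at 5..10

    def test_deletion_in_long_run_fires(self):
        v = _var(4, "CA", "C", [_csq("frameshift", 5)])
        res = rule_homopolymer_artifact(v, self.SEQ, THR)
        assert res.fired and res.strength == "artifact_uncertain"

    def test_run_of_five_no_fire(self):
        seq = "GGTC" + "AAAAA" + "CTGGGGG"
        v = _var(4, "CA", "C", [_csq("frameshift", 5)])
        assert not rule_homopolymer_artifact(v, seq, THR).fired

    def test_snv_excluded(self):
        v = _var(6, "A", "T", [_csq("nonsense", 6)])
        assert not rule_homopolymer_artifact(v, self.SEQ, THR).fired

    def test_non_homopolymer_unit_excluded(self):
        v = _var(4, "CAT", "C", [_csq("frameshift", 5)])
        assert not rule_homopolymer_artifact(v, self.SEQ, THR).fired


class TestAggregation:
    def _r(self, rid, fired, strength=None, category="x"):
        return RuleResult(rid, fired, strength, category if fired else None)

    def test_strong_dominates(self):
        rules = [self._r("nmd_escape", True, "not_lof_strong")]
        assert aggregate_verdict(rules) == "Not_LoF"

    def test_no_rules_is_lof(self):
        rules = [self._r("a", False), self._r("b", False)]
        assert aggregate_verdict(rules) == "LoF"

    def test_uncertain_only(self):
        rules = [self._r("low_pext", True, "uncertain")]
        assert aggregate_verdict(rules) == "Uncertain_LoF"

    def test_weak_without_strong(self):
        rules = [self._r("low_pext", True, "not_lof_weak")]
        assert aggregate_verdict(rules) == "Likely_not_LoF"

    def test_combination_category(self):
        rules = [
            RuleResult("a", True, "not_lof_strong", "last_exon_25"),
            RuleResult("b", True, "not_lof_weak", "low_pext"),
        ]
        v = aggregate_verdict(rules)
        assert aggregate_category(rules, v) == "combination_of_explanations"

    def test_monotonicity_adding_rescue_never_moves_toward_lof(self):
        order = {"LoF": 0, "Uncertain_LoF": 1, "Likely_not_LoF": 2, "Not_LoF": 3}
        base_sets = [
            [],
            [self._r("x", True, "uncertain")],
            [self._r("x", True, "not_lof_weak")],
            [self._r("x", True, "not_lof_strong")],
        ]
        for base in base_sets:
            before = aggregate_verdict(base)
            for strength in ("not_lof_weak", "not_lof_strong"):
                after = aggregate_verdict(
                    base + [RuleResult("y", True, strength, "cat")]
                )
                assert order[after] >= order[before]

    @pytest.mark.parametrize(
        "verdict,outcome",
        [
            ("Not_LoF", "explained"),
            ("Likely_not_LoF", "explained"),
            ("Uncertain_LoF", "uncertain"),
            ("LoF", "unexplained"),
            ("Likely_LoF", "unexplained"),
        ],
    )
    def test_outcome_mapping(self, verdict, outcome):
        assert classify_outcome(verdict) == outcome

    def test_unknown_verdict_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome("maybe")


class TestEngineOnCohort:
    def test_outcome_partition(self, curation_results):
        from ptriage.curation import outcome_tallies

        t = outcome_tallies(curation_results)
        assert sum(t.values()) == len(curation_results)

    def test_only_hc_plof_curated(self, cohort, curation_results):
        by_id = cohort.variants_by_id()
        for vid in curation_results:
            v = by_id[vid]
            assert v.loftee == "HC"
            assert any(c.is_plof for c in v.consequences)

    def test_chosen_transcript_recorded(self, cohort, curation_results):
        for res in curation_results.values():
            assert res.transcript_id in cohort.transcripts
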