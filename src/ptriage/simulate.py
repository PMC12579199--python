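"""Synthetic gnomAD-like cohort generator with planted, labeled scenarios.

Builds a fully self-contained mini-cohort — fabricated reference (one contig
per gene, ~12 kb each), gene models, multi-sample VCF, sample metadata, pext
track, SpliceAI-style delta scores, ClinVar-like table, PSI matrix and
genotype dosages — with every loss-of-function evasion scenario planted at a
known location and recorded in a truth table.  The truth table is the oracle
for the pipeline recovery tests: each planted pLoF variant carries its
expected verdict, explanation category and outcome group.

The generator is deterministic: identical (config, seed) pairs produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .genes import (
    CODON_TABLE,
    STOP_CODONS,
    TranscriptModel,
    reverse_complement,
)
from .variants import (
    GenotypeCall,
    GeneInfo,
    PextTrack,
    Sample,
    SpliceAnnotation,
    TranscriptConsequence,
    VariantRecord,
)

SCENARIO_KINDS = (
    "last_exon_25",
    "penultimate_50bp",
    "low_pext_rescue",
    "low_pext_uncertain",
    "mnv_rescue",
    "frame_restore_rescue",
    "splice_inframe_skip",
    "splice_alt_site",
    "splice_no_loss",
    "somatic_low_ab_ch",
    "homopolymer_artifact",
    "isoform_rescue",
    "true_lof_unexplained",
    "cis_rescue_haplotype",
    "project_cluster",
    "sqtl_exon",
)


class InfeasibleConfigError(ValueError):
    """Raised before any output when a config cannot be realized."""


@dataclass
class ScenarioSpec:
    """One planted scenario: kind, number of variants and carriers each."""

    kind: str
    n_variants: int = 1
    carriers: int = 2

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_variants > 0 and self.carriers < 1:
            raise ValueError("carrier count must be >= 1")


def default_scenarios() -> list[ScenarioSpec]:
    return [
        ScenarioSpec("last_exon_25", n_variants=2, carriers=2),
        ScenarioSpec("penultimate_50bp", n_variants=1, carriers=2),
        ScenarioSpec("low_pext_rescue", n_variants=2, carriers=2),
        ScenarioSpec("low_pext_uncertain", n_variants=1, carriers=2),
        ScenarioSpec("mnv_rescue", n_variants=1, carriers=3),
        ScenarioSpec("frame_restore_rescue", n_variants=1, carriers=2),
        ScenarioSpec("splice_inframe_skip", n_variants=1, carriers=2),
        ScenarioSpec("splice_alt_site", n_variants=1, carriers=2),
        ScenarioSpec("splice_no_loss", n_variants=1, carriers=2),
        ScenarioSpec("somatic_low_ab_ch", n_variants=2, carriers=5),
        ScenarioSpec("homopolymer_artifact", n_variants=1, carriers=2),
        ScenarioSpec("isoform_rescue", n_variants=1, carriers=2),
        ScenarioSpec("true_lof_unexplained", n_variants=2, carriers=2),
        ScenarioSpec("cis_rescue_haplotype", n_variants=1, carriers=35),
        ScenarioSpec("project_cluster", n_variants=1, carriers=3),
        ScenarioSpec("sqtl_exon", n_variants=1, carriers=3),
    ]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the analysed cohort: 500 genome-sequenced samples, ages
    from Normal(55, 12) truncated to [18, 95], somatic-variant carriers
    age-shifted by +15 years, planted pLoF variants at AC <= 5 apart from the
    cis-rescue haplotype (35 carriers, 34:1 concentrated in one ancestry
    group), and a small project-restricted cluster of putative cell-line
    artifacts.  A virtual exome stratum (AN = 200,000) mirrors a cohort whose
    exome arm dwarfs its genome arm, so that combined allele frequencies stay
    in the rare range.
    """

    n_samples: int = 500
    ancestry_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "nfe": 0.55, "afr": 0.15, "eas": 0.12, "amr": 0.10, "sas": 0.08
        }
    )
    main_project: str = "population_cohort"
    excluded_project: str = "cell_line_cohort"
    excluded_project_fraction: float = 0.05
    age_mean: float = 55.0
    age_sd: float = 12.0
    age_min: float = 18.0
    age_max: float = 95.0
    somatic_age_shift: float = 15.0
    an_exomes_virtual: int = 200_000
    cis_concentrated_ancestry: str = "eas"
    cis_minority_ancestry: str = "amr"
    sqtl_allele_freq: float = 0.3
    n_sqtl_null_variants: int = 4
    n_background_clinvar: int = 33
    scenarios: list[ScenarioSpec] = field(default_factory=default_scenarios)
    seed: int = 0

    def scenario(self, kind: str) -> ScenarioSpec | None:
        for s in self.scenarios:
            if s.kind == kind and s.n_variants > 0:
                return s
        return None


# ---------------------------------------------------------------------------
# Gene templates

_EXONS5 = [(1001, 1240), (1601, 1900), (2301, 2501), (2901, 3200), (3601, 4000)]
_CDS5 = [(1121, 1240), (1601, 1900), (2301, 2501), (2901, 3200), (3601, 3879)]
_EXONS4 = [(1001, 1240), (1601, 1900), (2901, 3200), (3601, 4000)]
_CDS4 = [(1121, 1240), (1601, 1900), (2901, 3200), (3601, 3882)]
CONTIG_LEN = 12_000

_BASES = "ACGT"
_NONSTOP_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS and c != "ATG")


def draw_ages(
    rng: np.random.Generator,
    n: int,
    mean: float = 55.0,
    sd: float = 12.0,
    lo: float = 18.0,
    hi: float = 95.0,
) -> np.ndarray:
    """Ages from a truncated normal via rejection, rounded to whole years."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return np.round(out)


def _random_seq(rng: np.random.Generator, length: int, max_run: int = 4) -> list[str]:
    """Random sequence with homopolymer runs capped (so the artifact rule
    only fires where a run is planted deliberately)."""
    seq: list[str] = []
    run = 0
    for _ in range(length):
        choices = _BASES
        if run >= max_run:
            choices = "".join(b for b in _BASES if b != seq[-1])
        b = choices[rng.integers(len(choices))]
        if seq and b == seq[-1]:
            run += 1
        else:
            run = 1
        seq.append(b)
    return seq


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """ATG + random internal non-stop codons + TAA."""
    body = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
        for _ in range(n_codons - 2)
    ]
    return ["ATG"] + body + ["TAA"]


def _write_cds_into(seq: list[str], tx: TranscriptModel, codons: list[str]) -> None:
    cds_seq = "".join(codons)
    assert len(cds_seq) == tx.cds_length
    if tx.strand == "-":
        cds_seq = reverse_complement(cds_seq)
    i = 0
    for a, b in tx.cds:
        seg = cds_seq[i : i + (b - a + 1)]
        seq[a - 1 : b] = list(seg)
        i += b - a + 1


def _avoid_homopolymers_in_codons(
    rng: np.random.Generator, codons: list[str], keep: set[int]
) -> None:
    """Resample internal codons until no run of >= 5 identical bases remains
    in the CDS (planted runs at indices in ``keep`` are preserved)."""
    for _ in range(200):
        s = "".join(codons)
        run_start, bad = 0, None
        for i in range(1, len(s) + 1):
            if i == len(s) or s[i] != s[run_start]:
                if i - run_start >= 5:
                    bad = (run_start, i)
                    break
                run_start = i
        if bad is None:
            return
        ci = bad[0] // 3
        if ci in keep or ci == 0 or ci >= len(codons) - 1:
            ci = min(bad[1] // 3, len(codons) - 2)
            if ci in keep or ci == 0:
                return  # planted run; leave as-is
        codons[ci] = _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
    raise AssertionError("could not remove accidental homopolymer runs")


def plant_mnv_pair(
    tx: TranscriptModel, contig_seq: str, codon_index: int
) -> tuple[tuple[int, str, str], tuple[int, str, str]]:
    """Find two SNVs in one codon where the first alone creates a stop codon
    but the joint doubly-mutated codon is not a stop.

    Returns two genomic SNVs ``(pos, ref, alt)``.  Raises ``ValueError``
    naming the codon when no such pair exists (verified by enumerating the
    codon table).
    """
    n_codons = tx.cds_length // 3
    if not 0 <= codon_index < n_codons:
        raise ValueError(f"codon index {codon_index} outside CDS (0..{n_codons - 1})")
    codon = tx.codon_at(contig_seq, codon_index)
    for p1 in range(3):
        for b1 in _BASES:
            if b1 == codon[p1]:
                continue
            single = codon[:p1] + b1 + codon[p1 + 1 :]
            if single not in STOP_CODONS:
                continue
            for p2 in range(3):
                if p2 == p1:
                    continue
                for b2 in _BASES:
                    if b2 == codon[p2]:
                        continue
                    joint = list(single)
                    joint[p2] = b2
                    if "".join(joint) in STOP_CODONS:
                        continue
                    snvs = []
                    for p, b in ((p1, b1), (p2, b2)):
                        off = 3 * codon_index + p + 1
                        pos = tx.genomic_of_cds_offset(off)
                        ref = contig_seq[pos - 1].upper()
                        alt = b if tx.strand == "+" else reverse_complement(b)
                        snvs.append((pos, ref, alt))
                    return snvs[0], snvs[1]
    raise ValueError(
        f"no stop-creating/rescuing SNV pair exists in codon {codon} "
        f"at index {codon_index}"
    )


# ---------------------------------------------------------------------------
# Generator internals


@dataclass
class _Plant:
    """One planted variant with its carriers and bookkeeping."""

    variant: VariantRecord
    scenario: str
    carriers: list[str]
    expected_verdict: str = "NA"
    expected_category: str = "NA"
    expected_outcome: str = "NA"
    somatic_ab: bool = False
    phase_partner: dict[str, str] = field(default_factory=dict)


class _Builder:
    def __init__(self, config: CohortConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.reference: dict[str, str] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        self.gene_contig: dict[str, str] = {}
        self.gene_info: list[GeneInfo] = []
        self.pext: dict[str, PextTrack] = {}
        self.splice: dict[str, SpliceAnnotation] = {}
        self.plants: list[_Plant] = []
        self.clinvar_rows: list[dict] = []
        self.extra_variants: list[VariantRecord] = []
        self.samples: list[Sample] = []
        self._used: set[str] = set()
        self._gene_counter = 0
        self.psi = pd.DataFrame()
        self.dosages = pd.DataFrame()
        self._dosage_calls: dict[str, dict[str, GenotypeCall]] = {}

    # -- samples -----------------------------------------------------------

    def build_samples(self) -> None:
        cfg, rng = self.cfg, self.rng
        groups = list(cfg.ancestry_fractions)
        probs = np.array([cfg.ancestry_fractions[g] for g in groups])
        probs = probs / probs.sum()
        ancestry = rng.choice(groups, size=cfg.n_samples, p=probs)
        n_excl = int(round(cfg.n_samples * cfg.excluded_project_fraction))
        project = np.array([cfg.main_project] * cfg.n_samples, dtype=object)
        excl_idx = rng.choice(cfg.n_samples, size=n_excl, replace=False)
        project[excl_idx] = cfg.excluded_project
        ages = draw_ages(
            rng, cfg.n_samples, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max
        )
        self.samples = [
            Sample(
                sample_id=f"S{i:04d}",
                ancestry_group=str(ancestry[i]),
                project=str(project[i]),
                age=float(ages[i]),
                data_type="genome",
            )
            for i in range(cfg.n_samples)
        ]
        order = rng.permutation(cfg.n_samples)
        self._shuffled = [self.samples[i] for i in order]

    def _take(self, n: int, pred) -> list[Sample]:
        out = []
        for s in self._shuffled:
            if len(out) == n:
                break
            if s.sample_id in self._used or not pred(s):
                continue
            out.append(s)
        if len(out) < n:
            raise InfeasibleConfigError(
                f"need {n} eligible carriers, only {len(out)} samples available"
            )
        for s in out:
            self._used.add(s.sample_id)
        return out

    def check_feasibility(self) -> None:
        cfg = self.cfg
        needed_main = 0
        for spec in cfg.scenarios:
            if spec.n_variants == 0:
                continue
            if spec.kind == "project_cluster":
                n_excl = int(round(cfg.n_samples * cfg.excluded_project_fraction))
                if spec.n_variants * spec.carriers > n_excl:
                    raise InfeasibleConfigError(
                        "project_cluster carriers exceed excluded-project samples"
                    )
            else:
                needed_main += spec.n_variants * spec.carriers
        if needed_main > cfg.n_samples:
            raise InfeasibleConfigError("more carriers requested than samples")

    # -- genes -------------------------------------------------------------

    def new_gene(
        self,
        pli: float = 0.99,
        loeuf: float = 0.2,
        omim: frozenset[str] = frozenset({"AD"}),
        is_ch: bool = False,
        in_panel: bool = True,
        strand: str = "+",
        isoform_gene: bool = False,
    ) -> tuple[str, TranscriptModel, list[str]]:
        """Create a gene + contig; returns (gene, MANE transcript, CDS codons)."""
        self._gene_counter += 1
        gene = f"G{self._gene_counter:02d}"
        contig = f"c{self._gene_counter:02d}"
        seq = _random_seq(self.rng, CONTIG_LEN)
        if isoform_gene:
            mane = TranscriptModel(
                transcript_id=f"tx_{gene}_mane", gene=gene, contig=contig,
                strand=strand, exons=list(_EXONS4), cds=list(_CDS4),
                mane_select=True,
            )
            nc = TranscriptModel(
                transcript_id=f"tx_{gene}_nc", gene=gene, contig=contig,
                strand=strand, exons=list(_EXONS5), cds=list(_CDS5),
                mane_select=False, noncoding_likely=True,
            )
            self.transcripts[nc.transcript_id] = nc
        else:
            mane = TranscriptModel(
                transcript_id=f"tx_{gene}_mane", gene=gene, contig=contig,
                strand=strand, exons=list(_EXONS5), cds=list(_CDS5),
                mane_select=True,
            )
        codons = _random_cds(self.rng, mane.cds_length // 3)
        _avoid_homopolymers_in_codons(self.rng, codons, keep=set())
        _write_cds_into(seq, mane, codons)
        self.reference[contig] = "".join(seq)
        self.transcripts[mane.transcript_id] = mane
        self.gene_contig[gene] = contig
        self.gene_info.append(
            GeneInfo(
                gene=gene, omim_patterns=omim, pli=pli, loeuf=loeuf,
                is_ch_gene=is_ch, in_panel=in_panel,
            )
        )
        # default pext: every exon near the gene maximum
        track = PextTrack(gene=gene)
        for ex in mane.exons:
            track.exon_scores[ex] = 0.9
        self.pext[gene] = track
        return gene, mane, codons

    def _set_ref_codon(self, tx: TranscriptModel, codon_index: int, codon: str) -> None:
        seq = list(self.reference[tx.contig])
        for p in range(3):
            off = 3 * codon_index + p + 1
            pos = tx.genomic_of_cds_offset(off)
            base = codon[p] if tx.strand == "+" else reverse_complement(codon[p])
            seq[pos - 1] = base
        self.reference[tx.contig] = "".join(seq)

    # -- variants ----------------------------------------------------------

    def _snv_at_offset(
        self, tx: TranscriptModel, cds_offset: int, cds_alt: str
    ) -> tuple[int, str, str]:
        pos = tx.genomic_of_cds_offset(cds_offset)
        ref = self.reference[tx.contig][pos - 1]
        alt = cds_alt if tx.strand == "+" else reverse_complement(cds_alt)
        if ref == alt:
            raise AssertionError("alt equals ref at planted SNV")
        return pos, ref, alt

    def plant_stop_gain(self, tx: TranscriptModel, cds_offset_codon3: int) -> tuple[int, str, str]:
        """Overlay a TAC codon ending at ``cds_offset_codon3`` and return the
        SNV (third codon base C>A) that creates a TAA stop."""
        assert cds_offset_codon3 % 3 == 0
        codon_index = cds_offset_codon3 // 3 - 1
        self._set_ref_codon(tx, codon_index, "TAC")
        return self._snv_at_offset(tx, cds_offset_codon3, "A")

    def add_plant(
        self,
        tx: TranscriptModel,
        pos: int,
        ref: str,
        alt: str,
        consequence: str,
        cds_offset: int | None,
        scenario: str,
        carriers: list[Sample],
        expected: tuple[str, str, str],
        loftee: str = "HC",
        somatic_ab: bool = False,
        clinvar: str | None = None,
        extra_consequences: list[TranscriptConsequence] | None = None,
    ) -> VariantRecord:
        cfg = self.cfg
        grp: dict[str, int] = {}
        for s in carriers:
            grp[s.ancestry_group] = grp.get(s.ancestry_group, 0) + 1
        csq = [
            TranscriptConsequence(
                transcript_id=tx.transcript_id, gene=tx.gene,
                consequence=consequence, cds_offset=cds_offset,
            )
        ] + (extra_consequences or [])
        v = VariantRecord(
            contig=tx.contig, pos=pos, ref=ref, alt=alt,
            ac_exomes=0, an_exomes=cfg.an_exomes_virtual,
            ac_genomes=len(carriers), an_genomes=2 * cfg.n_samples,
            pass_exomes=True, pass_genomes=True,
            ac_by_ancestry=grp, consequences=csq, loftee=loftee,
            clinvar_class=clinvar,
        )
        self.plants.append(
            _Plant(
                variant=v, scenario=scenario,
                carriers=[s.sample_id for s in carriers],
                expected_verdict=expected[0],
                expected_category=expected[1],
                expected_outcome=expected[2],
                somatic_ab=somatic_ab,
            )
        )
        return v

    # -- scenarios ---------------------------------------------------------

    def build_scenarios(self) -> None:
        cfg = self.cfg
        for spec in cfg.scenarios:
            for k in range(spec.n_variants):
                getattr(self, f"_plant_{spec.kind}")(spec, k)

    def _germline_carriers(self, n: int) -> list[Sample]:
        return self._take(n, lambda s: s.project == self.cfg.main_project)

    def _plant_last_exon_25(self, spec: ScenarioSpec, k: int) -> None:
        strand = "-" if k % 2 == 1 else "+"
        gene, tx, _ = self.new_gene(strand=strand)
        pos, ref, alt = self.plant_stop_gain(tx, 1101)  # removes 100/1200 of CDS
        self.add_plant(
            tx, pos, ref, alt, "nonsense", 1101, "last_exon_25",
            self._germline_carriers(spec.carriers),
            ("Not_LoF", "last_exon_25", "explained"),
        )

    def _plant_penultimate_50bp(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, _ = self.new_gene()
        # offset 912 is 9 coding bp from the penultimate exon's 3' junction
        # and removes 289/1200 = 24.1% of the CDS
        pos, ref, alt = self.plant_stop_gain(tx, 912)
        self.add_plant(
            tx, pos, ref, alt, "nonsense", 912, "penultimate_50bp",
            self._germline_carriers(spec.carriers),
            ("Not_LoF", "last_exon_25", "explained"),
        )

    def _plant_low_pext(self, spec: ScenarioSpec, relative: float, expected) -> None:
        gene, tx, _ = self.new_gene()
        exon2 = tx.exons[1]
        self.pext[gene].exon_scores[exon2] = round(relative * 0.9, 6)
        pos, ref, alt = self.plant_stop_gain(tx, 300)
        self.add_plant(
            tx, pos, ref, alt, "nonsense", 300,
            "low_pext_rescue" if relative <= 0.2 else "low_pext_uncertain",
            self._germline_carriers(spec.carriers), expected,
        )

    def _plant_low_pext_rescue(self, spec: ScenarioSpec, k: int) -> None:
        self._plant_low_pext(spec, 0.15, ("Likely_not_LoF", "low_pext", "explained"))

    def _plant_low_pext_uncertain(self, spec: ScenarioSpec, k: int) -> None:
        self._plant_low_pext(spec, 0.4, ("Uncertain_LoF", "NA", "uncertain"))

    def _plant_mnv_rescue(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, _ = self.new_gene()
        codon_index = 100
        self._set_ref_codon(tx, codon_index, "CGA")
        (p1, r1, a1), (p2, r2, a2) = plant_mnv_pair(
            tx, self.reference[tx.contig], codon_index
        )
        carriers = self._germline_carriers(spec.carriers)
        off1 = tx.cds_offset_of(p1)
        off2 = tx.cds_offset_of(p2)
        self.add_plant(
            tx, p1, r1, a1, "nonsense", off1, "mnv_rescue", carriers,
            ("Not_LoF", "mnv", "explained"),
        )
        partner_alone = self._joint_codon(tx, codon_index, {off2: a2})
        ref_codon = tx.codon_at(self.reference[tx.contig], codon_index)
        partner_cls = (
            "synonymous"
            if CODON_TABLE[partner_alone] == CODON_TABLE[ref_codon]
            else "missense"
        )
        self.add_plant(
            tx, p2, r2, a2, partner_cls, off2, "mnv_rescue", carriers,
            ("NA", "NA", "NA"), loftee="NA",
        )

    def _joint_codon(self, tx, codon_index, cds_alts: dict[int, str]) -> str:
        codon = list(tx.codon_at(self.reference[tx.contig], codon_index))
        for off, genomic_alt in cds_alts.items():
            p = (off - 1) % 3
            codon[p] = (
                genomic_alt if tx.strand == "+" else reverse_complement(genomic_alt)
            )
        return "".join(codon)

    def _plant_frame_restore_rescue(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, codons = self.new_gene()
        # 1-bp deletion at CDS offset 201, 1-bp insertion at 231 (net 0);
        # resample the intervening codons until the shifted frame is stop-free
        del_off, ins_off = 201, 231
        for _ in range(100):
            cds = tx.cds_sequence(self.reference[tx.contig])
            shifted = cds[: del_off - 1] + cds[del_off:]
            seg = shifted[del_off - 1 : ins_off - 1]
            frame_ok = all(
                seg[i : i + 3] not in STOP_CODONS for i in range(0, len(seg) - 2, 3)
            )
            prev_differs = cds[del_off - 2] != cds[del_off - 1]
            if frame_ok and prev_differs:
                break
            for ci in range((del_off - 1) // 3, ins_off // 3 + 1):
                if 0 < ci < len(codons) - 1:
                    codons[ci] = _NONSTOP_CODONS[self.rng.integers(len(_NONSTOP_CODONS))]
            seq = list(self.reference[tx.contig])
            _write_cds_into(seq, tx, codons)
            self.reference[tx.contig] = "".join(seq)
        else:
            raise AssertionError("could not build stop-free shifted frame")

        contig_seq = self.reference[tx.contig]
        carriers = self._germline_carriers(spec.carriers)
        # deletion: anchor at the base before the deleted one
        pos_del = tx.genomic_of_cds_offset(del_off)
        pos_anchor = pos_del - 1 if tx.strand == "+" else pos_del
        ref_del = contig_seq[pos_anchor - 1 : pos_anchor + 1]
        self.add_plant(
            tx, pos_anchor, ref_del, ref_del[0], "frameshift", del_off,
            "frame_restore_rescue", carriers,
            ("Not_LoF", "frame_restore", "explained"),
        )
        # insertion: duplicate-free inserted base after CDS offset ins_off
        pos_ins = tx.genomic_of_cds_offset(ins_off)
        anchor = contig_seq[pos_ins - 1]
        # inserted base differs from both neighbours so the record is stable
        # under left-alignment
        inserted = next(
            b for b in _BASES if b != anchor and b != contig_seq[pos_ins - 2]
        )
        self.add_plant(
            tx, pos_ins, anchor, anchor + inserted, "frameshift", ins_off,
            "frame_restore_rescue", carriers,
            ("Not_LoF", "frame_restore", "explained"),
        )

    def _splice_variant(self, tx: TranscriptModel, pos: int) -> tuple[int, str, str]:
        ref = self.reference[tx.contig][pos - 1]
        alt = next(b for b in _BASES if b != ref)
        return pos, ref, alt

    def _plant_splice_inframe_skip(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, _ = self.new_gene()
        exon3 = tx.exons[2]  # 201 coding bp: in-frame, 16.8% of the CDS
        pos, ref, alt = self._splice_variant(tx, exon3[1] + 1)
        v = self.add_plant(
            tx, pos, ref, alt, "essential_splice", None, "splice_inframe_skip",
            self._germline_carriers(spec.carriers),
            ("Not_LoF", "inframe_exon_skip_25", "explained"),
        )
        self.splice[v.variant_id] = SpliceAnnotation(
            variant_id=v.variant_id, donor_loss=0.91, donor_loss_pos=-1
        )

    def _plant_splice_alt_site(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, _ = self.new_gene()
        exon2 = tx.exons[1]  # 300 coding bp: exactly 25%, skip rescue fails
        pos, ref, alt = self._splice_variant(tx, exon2[1] + 1)
        v = self.add_plant(
            tx, pos, ref, alt, "essential_splice", None, "splice_alt_site",
            self._germline_carriers(spec.carriers),
            ("Not_LoF", "inframe_alt_site", "explained"),
        )
        self.splice[v.variant_id] = SpliceAnnotation(
            variant_id=v.variant_id,
            donor_loss=0.85, donor_loss_pos=-1,
            donor_gain=0.6, donor_gain_pos=-21,
        )

    def _plant_splice_no_loss(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, _ = self.new_gene()
        exon4 = tx.exons[3]
        pos, ref, alt = self._splice_variant(tx, exon4[0] - 1)
        v = self.add_plant(
            tx, pos, ref, alt, "essential_splice", None, "splice_no_loss",
            self._germline_carriers(spec.carriers),
            ("Likely_not_LoF", "no_loss_detected", "explained"),
        )
        self.splice[v.variant_id] = SpliceAnnotation(
            variant_id=v.variant_id, acceptor_loss=0.03, donor_loss=0.05,
            acceptor_loss_pos=1,
        )

    def _plant_somatic_low_ab_ch(self, spec: ScenarioSpec, k: int) -> None:
        cfg = self.cfg
        gene, tx, _ = self.new_gene(is_ch=True)
        carriers = self._germline_carriers(spec.carriers)
        shifted = draw_ages(
            self.rng, len(carriers), cfg.age_mean + cfg.somatic_age_shift,
            cfg.age_sd, cfg.age_min, cfg.age_max,
        )
        for s, age in zip(carriers, shifted):
            s.age = float(age)
        pos, ref, alt = self.plant_stop_gain(tx, 150)
        self.add_plant(
            tx, pos, ref, alt, "nonsense", 150, "somatic_low_ab_ch", carriers,
            ("LoF", "NA", "unexplained"), somatic_ab=True,
        )

    def _plant_homopolymer_artifact(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, codons = self.new_gene()
        # plant AAA AAA A.. : a 7-base A run at CDS offsets 181..187
        codons[60], codons[61] = "AAA", "AAA"
        codons[62] = "A" + "TT"
        if codons[59][-1] == "A":
            codons[59] = codons[59][:-1] + "G"
        seq = list(self.reference[tx.contig])
        _write_cds_into(seq, tx, codons)
        self.reference[tx.contig] = "".join(seq)
        contig_seq = self.reference[tx.contig]
        # delete one A; anchor on the preceding (non-A) base
        first_a = tx.genomic_of_cds_offset(181 if tx.strand == "+" else 187)
        pos_anchor = first_a - 1
        ref = contig_seq[pos_anchor - 1 : pos_anchor + 1]
        self.add_plant(
            tx, pos_anchor, ref, ref[0], "frameshift", 181,
            "homopolymer_artifact",
            self._germline_carriers(spec.carriers),
            ("Uncertain_LoF", "NA", "uncertain"),
        )

    def _plant_isoform_rescue(self, spec: ScenarioSpec, k: int) -> None:
        gene, mane, _ = self.new_gene(isoform_gene=True)
        nc = self.transcripts[f"tx_{gene}_nc"]
        contig_seq = self.reference[nc.contig]
        # find a codon in the nc-only exon where one SNV creates a stop
        exon3 = nc.exons[2]
        target = None
        for off in range(421, 620, 3):  # nc CDS offsets inside exon3
            ci = (off - 1) // 3
            codon = nc.codon_at(contig_seq, ci)
            for p in range(3):
                for b in _BASES:
                    if b != codon[p] and codon[:p] + b + codon[p + 1 :] in STOP_CODONS:
                        target = (ci, p, b)
                        break
                if target:
                    break
            if target:
                break
        assert target is not None, "no stop-creatable codon in isoform exon"
        ci, p, b = target
        off = 3 * ci + p + 1
        pos, ref, alt = self._snv_at_offset(nc, off, b)
        self.add_plant(
            nc, pos, ref, alt, "nonsense", off, "isoform_rescue",
            self._germline_carriers(spec.carriers),
            ("Likely_not_LoF", "noncoding_isoform", "explained"),
        )

    def _plant_true_lof_unexplained(self, spec: ScenarioSpec, k: int) -> None:
        gene, tx, _ = self.new_gene()
        pos, ref, alt = self.plant_stop_gain(tx, 150)
        self.add_plant(
            tx, pos, ref, alt, "nonsense", 150, "true_lof_unexplained",
            self._germline_carriers(spec.carriers),
            ("LoF", "NA", "unexplained"),
        )

    def _plant_project_cluster(self, spec: ScenarioSpec, k: int) -> None:
        cfg = self.cfg
        gene, tx, _ = self.new_gene()
        carriers = self._take(
            spec.carriers, lambda s: s.project == cfg.excluded_project
        )
        pos, ref, alt = self.plant_stop_gain(tx, 150)
        self.add_plant(
            tx, pos, ref, alt, "nonsense", 150, "project_cluster", carriers,
            ("LoF", "NA", "unexplained"),
        )

    def _plant_cis_rescue_haplotype(self, spec: ScenarioSpec, k: int) -> None:
        cfg = self.cfg
        gene, tx, _ = self.new_gene(
            pli=0.2, loeuf=1.97, omim=frozenset({"AD", "AR"}), in_panel=False
        )
        n_major = spec.carriers - 1 if spec.carriers > 1 else spec.carriers
        carriers = self._take(
            n_major,
            lambda s: s.project == cfg.main_project
            and s.ancestry_group == cfg.cis_concentrated_ancestry,
        )
        if spec.carriers > 1:
            carriers += self._take(
                1,
                lambda s: s.project == cfg.main_project
                and s.ancestry_group == cfg.cis_minority_ancestry,
            )
        # dominant-negative missense: overlay GGA->GAA (Gly->Glu) at codon 44
        self._set_ref_codon(tx, 44, "GGA")
        pos_m, ref_m, alt_m = self._snv_at_offset(tx, 134, "A")
        plp = self.add_plant(
            tx, pos_m, ref_m, alt_m, "missense", 134, "cis_rescue_haplotype",
            carriers, ("NA", "NA", "NA"), loftee="NA", clinvar="Pathogenic",
        )
        # downstream nonsense modifier: TAC -> TAA at codon 135
        pos_n, ref_n, alt_n = self.plant_stop_gain(tx, 408)
        modifier = self.add_plant(
            tx, pos_n, ref_n, alt_n, "nonsense", 408, "cis_rescue_haplotype",
            carriers, ("LoF", "NA", "unexplained"), clinvar="Pathogenic",
        )
        # read-backed phase annotation available for one carrier
        self.plants[-2].phase_partner[carriers[0].sample_id] = modifier.variant_id
        self.plants[-1].phase_partner[carriers[0].sample_id] = plp.variant_id
        self.clinvar_rows.append(
            {
                "variant_id": plp.variant_id, "gene": gene,
                "clinical_significance": "Pathogenic", "mechanism": "GoF",
            }
        )
        self.clinvar_rows.append(
            {
                "variant_id": modifier.variant_id, "gene": gene,
                "clinical_significance": "Pathogenic", "mechanism": "LoF",
            }
        )

    def _plant_sqtl_exon(self, spec: ScenarioSpec, k: int) -> None:
        cfg, rng = self.cfg, self.rng
        gene, tx, _ = self.new_gene()
        exon3 = tx.exons[2]
        self.pext[gene].exon_scores[exon3] = round(0.4 * 0.9, 6)  # pext-concordant
        contig = tx.contig
        # non-coding sQTL variant with population-scale frequency
        sqtl_pos = 8000
        ref = self.reference[contig][sqtl_pos - 1]
        alt = next(b for b in _BASES if b != ref)
        p = cfg.sqtl_allele_freq
        dosage = rng.choice(
            [0, 1, 2], size=cfg.n_samples,
            p=[(1 - p) ** 2, 2 * p * (1 - p), p**2],
        )
        sample_ids = [s.sample_id for s in self.samples]
        calls: dict[str, GenotypeCall] = {}
        grp: dict[str, int] = {}
        vid = f"{contig}-{sqtl_pos}-{ref}-{alt}"
        for s, d in zip(self.samples, dosage):
            gt = {0: "hom_ref", 1: "het", 2: "hom_alt"}[int(d)]
            dp = int(max(10, rng.poisson(30)))
            ad_alt = {0: 0, 1: dp // 2, 2: dp}[int(d)]
            calls[s.sample_id] = GenotypeCall(
                sample_id=s.sample_id, variant_id=vid, gt=gt, dp=dp, gq=99,
                ad_ref=dp - ad_alt, ad_alt=ad_alt,
            )
            if d:
                grp[s.ancestry_group] = grp.get(s.ancestry_group, 0) + int(d)
        ac = int(dosage.sum())
        sqtl_v = VariantRecord(
            contig=contig, pos=sqtl_pos, ref=ref, alt=alt,
            ac_exomes=0, an_exomes=cfg.an_exomes_virtual,
            ac_genomes=ac, an_genomes=2 * cfg.n_samples,
            pass_exomes=True, pass_genomes=True, ac_by_ancestry=grp,
            consequences=[
                TranscriptConsequence(
                    transcript_id=tx.transcript_id, gene=gene,
                    consequence="other", cds_offset=None,
                )
            ],
            loftee="NA",
        )
        self.extra_variants.append(sqtl_v)
        self._dosage_calls[vid] = calls
        # pLoF inside the sQTL-responsive exon, carried by sQTL-het samples
        het_ids = {s for s, c in calls.items() if c.gt == "het"}
        carriers = self._take(
            spec.carriers,
            lambda s: s.project == cfg.main_project and s.sample_id in het_ids,
        )
        pos, ref2, alt2 = self.plant_stop_gain(tx, 501)
        self.add_plant(
            tx, pos, ref2, alt2, "nonsense", 501, "sqtl_exon", carriers,
            ("Uncertain_LoF", "NA", "uncertain"),
        )
        self.plants[-1]._sqtl_vid = vid  # type: ignore[attr-defined]
        # PSI matrix: causal exon responds to dosage, flanking exons do not
        exon_ids = [f"{contig}:{a}-{b}" for a, b in tx.exons[1:4]]
        psi = np.empty((3, cfg.n_samples))
        psi[0] = np.clip(0.95 + rng.normal(0, 0.03, cfg.n_samples), 0, 1)
        psi[1] = np.clip(
            0.92 - 0.25 * dosage + rng.normal(0, 0.04, cfg.n_samples), 0, 1
        )
        psi[2] = np.clip(0.95 + rng.normal(0, 0.03, cfg.n_samples), 0, 1)
        self.psi = pd.DataFrame(psi, index=exon_ids, columns=sample_ids)
        self.psi.index.name = "exon_id"
        # dosage table: the causal variant plus null candidates in the window
        rows = {vid: dosage}
        for j in range(cfg.n_sqtl_null_variants):
            npos = 6000 + 37 * j
            nref = self.reference[contig][npos - 1]
            nalt = next(b for b in _BASES if b != nref)
            q = 0.2 + 0.05 * j
            rows[f"{contig}-{npos}-{nref}-{nalt}"] = rng.choice(
                [0, 1, 2], size=cfg.n_samples,
                p=[(1 - q) ** 2, 2 * q * (1 - q), q**2],
            )
        self.dosages = pd.DataFrame(rows).T
        self.dosages.columns = sample_ids
        self.dosages.index.name = "variant_id"

    # -- genotypes & assembly ----------------------------------------------

    def _carrier_call(self, sample_id: str, vid: str, somatic: bool) -> GenotypeCall:
        rng = self.rng
        dp = int(max(10, rng.poisson(30)))
        if somatic:
            for _ in range(50):
                ad_alt = int(round(dp * rng.uniform(0.27, 0.33)))
                if 0.25 < ad_alt / dp < 0.35:
                    break
        else:
            lo, hi = int(np.ceil(0.4 * dp)), int(np.floor(0.6 * dp))
            ad_alt = int(rng.integers(lo, hi + 1))
        return GenotypeCall(
            sample_id=sample_id, variant_id=vid, gt="het", dp=dp,
            gq=int(rng.integers(60, 100)), ad_ref=dp - ad_alt, ad_alt=ad_alt,
        )

    def build_background_clinvar(self) -> None:
        """Landscape-only ClinVar-like rows: a spread of raw classifications,
        allele frequencies and presence states (genome, exome-only, absent)."""
        cfg, rng = self.cfg, self.rng
        if cfg.n_background_clinvar == 0 or not self.gene_contig:
            return
        raw_classes = [
            ("Pathogenic", 6), ("Likely pathogenic", 3),
            ("Pathogenic/Likely pathogenic", 2),
            ("Uncertain significance", 8),
            ("Benign", 4), ("Likely benign", 3), ("Benign/Likely benign", 2),
            ("Conflicting interpretations of pathogenicity", 3),
            ("drug response", 1), ("not provided", 1),
        ]
        flat = [c for c, n in raw_classes for _ in range(n)]
        flat = flat[: cfg.n_background_clinvar]
        contigs = sorted(self.gene_contig.values())
        gene_of = {c: g for g, c in self.gene_contig.items()}
        consequences = ["missense", "synonymous", "intronic", "other"]
        # exome ACs chosen to spread the AC and AF histograms
        ac_pool = [1, 1, 1, 1, 2, 3, 5, 5, 8, 10, 25, 60, 150, 900, 5000, 50000]
        for i, raw in enumerate(flat):
            contig = contigs[i % len(contigs)]
            pos = 9013 + 17 * i
            ref = self.reference[contig][pos - 1]
            alt = next(b for b in _BASES if b != ref)
            vid = f"{contig}-{pos}-{ref}-{alt}"
            state = i % 3  # 0: exome-present, 1: exome-present, 2: absent
            self.clinvar_rows.append(
                {
                    "variant_id": vid, "gene": gene_of[contig],
                    "clinical_significance": raw, "mechanism": "unknown",
                }
            )
            if state == 2:
                continue
            ac = int(ac_pool[int(rng.integers(len(ac_pool)))])
            self.extra_variants.append(
                VariantRecord(
                    contig=contig, pos=pos, ref=ref, alt=alt,
                    ac_exomes=ac, an_exomes=cfg.an_exomes_virtual,
                    ac_genomes=0, an_genomes=2 * cfg.n_samples,
                    pass_exomes=True, pass_genomes=i % 6 != 0,
                    ac_by_ancestry={"nfe": ac},
                    consequences=[
                        TranscriptConsequence(
                            transcript_id=f"tx_{gene_of[contig]}_mane",
                            gene=gene_of[contig],
                            consequence=consequences[i % 4],
                            cds_offset=None,
                        )
                    ],
                    loftee="NA",
                    clinvar_class=raw,
                )
            )

    def assemble(self) -> pio.Cohort:
        cfg = self.cfg
        sample_ids = [s.sample_id for s in self.samples]
        variants: list[VariantRecord] = []
        genotypes: dict[str, dict[str, GenotypeCall]] = {}
        truth_rows = []
        for plant in self.plants:
            v = plant.variant
            vid = v.variant_id
            variants.append(v)
            calls = {}
            for sid in plant.carriers:
                call = self._carrier_call(sid, vid, plant.somatic_ab)
                if sid in plant.phase_partner:
                    call.phase_partner = plant.phase_partner[sid]
                calls[sid] = call
            genotypes[vid] = calls
            truth_rows.append(
                {
                    "variant_id": vid,
                    "scenario": plant.scenario,
                    "expected_verdict": plant.expected_verdict,
                    "expected_category": plant.expected_category,
                    "expected_outcome": plant.expected_outcome,
                }
            )
        for v in self.extra_variants:
            variants.append(v)
            genotypes[v.variant_id] = self._dosage_calls.get(v.variant_id, {})
        truth = pd.DataFrame(
            truth_rows,
            columns=[
                "variant_id", "scenario", "expected_verdict",
                "expected_category", "expected_outcome",
            ],
        )
        clinvar = pd.DataFrame(
            self.clinvar_rows,
            columns=["variant_id", "gene", "clinical_significance", "mechanism"],
        )
        return pio.Cohort(
            reference=self.reference,
            variants=variants,
            genotypes=genotypes,
            sample_ids=sample_ids,
            samples=self.samples,
            transcripts=self.transcripts,
            gene_info={g.gene: g for g in self.gene_info},
            pext=self.pext,
            splice=self.splice,
            clinvar=clinvar,
            psi=self.psi,
            dosages=self.dosages,
            truth=truth,
        )


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> pio.Cohort:
    """Generate the synthetic cohort; optionally write all files to a directory.

    ``seed`` overrides ``config.seed`` when given.  Raises
    :class:`InfeasibleConfigError` before producing any output when the
    requested carriers cannot be realized.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    builder = _Builder(config)
    builder.check_feasibility()
    builder.build_samples()
    builder.build_scenarios()
    builder.build_background_clinvar()
    cohort = builder.assemble()
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: pio.Cohort, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    f = pio.COHORT_FILES
    pio.write_fasta(cohort.reference, d / f["reference"])
    contigs = {c: len(s) for c, s in cohort.reference.items()}
    pio.write_vcf(
        d / f["vcf"], cohort.variants, cohort.genotypes, cohort.sample_ids, contigs
    )
    pio.write_samples(cohort.samples, d / f["samples"])
    pio.write_gtf(list(cohort.transcripts.values()), d / f["gtf"])
    pio.write_gene_info(list(cohort.gene_info.values()), d / f["gene_info"])
    gene_contig = {
        t.gene: t.contig for t in cohort.transcripts.values()
    }
    pio.write_pext(cohort.pext, gene_contig, d / f["pext"])
    pio.write_splice(cohort.splice, d / f["splice"])
    pio.write_clinvar(cohort.clinvar, d / f["clinvar"])
    if not cohort.psi.empty:
        pio.write_matrix(cohort.psi, d / f["psi"])
    if not cohort.dosages.empty:
        pio.write_matrix(cohort.dosages, d / f["dosages"])
    pio.write_truth(cohort.truth, d / f["truth"])
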