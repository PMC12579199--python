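"""Shared variant-level domain types and identifier conventions.

Positions are VCF-style 1-based throughout the package.  Variant identity is
the canonical ``contig-pos-ref-alt`` string; indels are reduced to minimal
representation (shared-suffix then shared-prefix trimming) on ingest so that
co-occurrence joins by identifier are well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class VariantIdError(ValueError):
    """Raised for malformed canonical variant identifiers."""


_VALID_BASES = set("ACGTN")


def parse_variant_id(id_string: str) -> tuple[str, int, str, str]:
    """Split a canonical ``contig-pos-ref-alt`` identifier into its fields.

    The contig itself may not contain ``-``; positions are 1-based.  Raises
    :class:`VariantIdError` naming the offending field for malformed input.
    """
    if not id_string:
        raise VariantIdError("empty identifier")
    parts = id_string.split("-")
    if len(parts) != 4:
        raise VariantIdError(
            f"expected 4 '-'-separated fields (contig-pos-ref-alt), got "
            f"{len(parts)} in {id_string!r}"
        )
    contig, pos_s, ref, alt = parts
    if not contig:
        raise VariantIdError(f"empty contig in {id_string!r}")
    if not pos_s.isdigit():
        raise VariantIdError(f"non-numeric position {pos_s!r} in {id_string!r}")
    if not ref:
        raise VariantIdError(f"empty ref allele in {id_string!r}")
    if not alt:
        raise VariantIdError(f"empty alt allele in {id_string!r}")
    for label, allele in (("ref", ref), ("alt", alt)):
        if any(b not in _VALID_BASES for b in allele.upper()):
            raise VariantIdError(
                f"invalid {label} allele {allele!r} in {id_string!r}"
            )
    return contig, int(pos_s), ref.upper(), alt.upper()


def format_variant_id(contig: str, pos: int, ref: str, alt: str) -> str:
    return f"{contig}-{pos}-{ref.upper()}-{alt.upper()}"


def minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping at least one base each.

    This yields the parsimonious left-aligned representation for variants that
    do not sit inside repeat context; full left-alignment against a reference
    is applied by the VCF reader when a FASTA is available.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(pos: int, ref: str, alt: str, contig_seq: str) -> tuple[int, str, str]:
    """Left-align an indel against the contig sequence (1-based pos).

    Pure insertions/deletions anchored on a shared first base are shifted left
    while the flanking base allows; SNVs and complex substitutions are
    returned unchanged (after minimal representation).
    """
    ref, alt = ref.upper(), alt.upper()
    # classic normalization: truncate shared last bases, extending left from
    # the reference whenever an allele would become empty
    while ref and alt and ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if pos == 1:
                break
            pos -= 1
            b = contig_seq[pos - 1].upper()
            ref = b + ref[:-1]
            alt = b + alt[:-1]
        else:
            ref = ref[:-1]
            alt = alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class TranscriptConsequence:
    """Predicted consequence of one variant on one transcript."""

    transcript_id: str
    gene: str
    consequence: str  # nonsense | frameshift | essential_splice | missense |
    #                   synonymous | intronic | other
    cds_offset: int | None = None  # 1-based offset within the CDS

    PLOF_CLASSES = frozenset({"nonsense", "frameshift", "essential_splice"})

    @property
    def is_plof(self) -> bool:
        return self.consequence in self.PLOF_CLASSES


@dataclass
class VariantRecord:
    """One site/allele with cohort-level counts and annotations."""

    contig: str
    pos: int
    ref: str
    alt: str
    ac_exomes: int | None = None
    an_exomes: int | None = None
    ac_genomes: int | None = None
    an_genomes: int | None = None
    pass_exomes: bool | None = None
    pass_genomes: bool | None = None
    ac_by_ancestry: dict[str, int] = field(default_factory=dict)
    consequences: list[TranscriptConsequence] = field(default_factory=list)
    loftee: str = "NA"  # HC | LC | NA
    clinvar_class: str | None = None

    def __post_init__(self) -> None:
        for ac, an, label in (
            (self.ac_exomes, self.an_exomes, "exomes"),
            (self.ac_genomes, self.an_genomes, "genomes"),
        ):
            if ac is not None and ac < 0:
                raise ValueError(f"negative AC ({label})")
            if ac is not None and an is not None and ac > an:
                raise ValueError(f"AC > AN ({label}): {ac} > {an}")
        if self.pass_exomes is None and self.pass_genomes is None:
            raise ValueError("at least one of pass_exomes/pass_genomes required")

    @property
    def variant_id(self) -> str:
        return format_variant_id(self.contig, self.pos, self.ref, self.alt)

    @property
    def total_ac(self) -> int:
        return (self.ac_exomes or 0) + (self.ac_genomes or 0)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def combined_af(self) -> float:
        return combined_af(
            self.ac_exomes, self.an_exomes, self.ac_genomes, self.an_genomes
        )

    def consequence_on(self, transcript_id: str) -> TranscriptConsequence | None:
        for c in self.consequences:
            if c.transcript_id == transcript_id:
                return c
        return None


def combined_af(
    ac_ex: int | None,
    an_ex: int | None,
    ac_ge: int | None,
    an_ge: int | None,
) -> float:
    """Allele frequency pooled over exome and genome call sets.

    When a variant was detected by only one sequencing method, the AF of that
    method alone is returned.  Zero total AN is an error.
    """
    have_ex = ac_ex is not None and an_ex is not None
    have_ge = ac_ge is not None and an_ge is not None
    if not have_ex and not have_ge:
        raise ValueError("no allele-number data in either data type")
    ac = (ac_ex if have_ex else 0) + (ac_ge if have_ge else 0)
    an = (an_ex if have_ex else 0) + (an_ge if have_ge else 0)
    for a, n in ((ac_ex, an_ex), (ac_ge, an_ge)):
        if a is not None and n is not None and a > n:
            raise ValueError(f"AC {a} exceeds AN {n}")
    if an == 0:
        raise ValueError("total AN is zero")
    return ac / an


@dataclass
class GenotypeCall:
    """One sample x variant genotype with its quality annotations."""

    sample_id: str
    variant_id: str
    gt: str  # het | hom_alt | hom_ref | missing
    dp: int | None = None
    gq: int | None = None
    ad_ref: int | None = None
    ad_alt: int | None = None
    phase_partner: str | None = None

    def __post_init__(self) -> None:
        if self.gt not in {"het", "hom_alt", "hom_ref", "missing"}:
            raise ValueError(f"invalid genotype {self.gt!r}")
        for name in ("dp", "gq", "ad_ref", "ad_alt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"negative {name}: {v}")

    @property
    def is_carrier(self) -> bool:
        return self.gt in ("het", "hom_alt")

    @property
    def n_alt_alleles(self) -> int:
        return {"het": 1, "hom_alt": 2}.get(self.gt, 0)

    def allele_balance(self) -> float | None:
        return allele_balance(self.ad_ref, self.ad_alt)


def allele_balance(ad_ref: int | None, ad_alt: int | None) -> float | None:
    """Fraction of reads supporting the alternate allele; None when no reads."""
    if ad_ref is None or ad_alt is None:
        return None
    if ad_ref < 0 or ad_alt < 0:
        raise ValueError("negative allelic depth")
    denom = ad_ref + ad_alt
    if denom == 0:
        return None
    ab = ad_alt / denom
    assert 0.0 <= ab <= 1.0
    return ab


@dataclass
class Sample:
    """One sequenced individual."""

    sample_id: str
    ancestry_group: str
    project: str
    age: float | None = None
    data_type: str = "genome"  # genome | exome

    def __post_init__(self) -> None:
        if self.age is not None and (self.age < 0 or math.isnan(self.age)):
            raise ValueError(f"invalid age {self.age}")
        if self.data_type not in ("genome", "exome"):
            raise ValueError(f"invalid data_type {self.data_type!r}")


@dataclass
class GeneInfo:
    """Gene-level annotations: inheritance, constraint, panel membership."""

    gene: str
    omim_patterns: frozenset[str] = frozenset()  # subset of {AD, AR, XL, other}
    pli: float | None = None
    loeuf: float | None = None
    is_ch_gene: bool = False
    in_panel: bool = False

    def __post_init__(self) -> None:
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pLI out of [0,1]: {self.pli}")
        if self.loeuf is not None and self.loeuf < 0:
            raise ValueError(f"negative LOEUF: {self.loeuf}")


@dataclass
class PextTrack:
    """Per-exon mean expression-proportion (pext) scores for one gene.

    Keys are 1-based inclusive exon intervals on the gene's contig.
    """

    gene: str
    exon_scores: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iv, s in self.exon_scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"pext score out of [0,1] at {iv}: {s}")

    @property
    def gene_max(self) -> float:
        return max(self.exon_scores.values(), default=0.0)

    def score_at(self, pos: int) -> float | None:
        for (start, end), s in self.exon_scores.items():
            if start <= pos <= end:
                return s
        return None

    def relative_score_at(self, pos: int) -> float | None:
        """Exon score divided by the gene's maximum exon score."""
        s = self.score_at(pos)
        gmax = self.gene_max
        if s is None or gmax == 0:
            return None
        return s / gmax


@dataclass
class SpliceAnnotation:
    """SpliceAI-style delta scores with signed positional offsets (bp)."""

    variant_id: str
    acceptor_gain: float = 0.0
    acceptor_loss: float = 0.0
    donor_gain: float = 0.0
    donor_loss: float = 0.0
    acceptor_gain_pos: int = 0
    acceptor_loss_pos: int = 0
    donor_gain_pos: int = 0
    donor_loss_pos: int = 0

    def __post_init__(self) -> None:
        for name in ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"delta score {name} out of [0,1]: {v}")

    @property
    def max_loss(self) -> float:
        return max(self.acceptor_loss, self.donor_loss)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention for all printed summaries)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage under the package rounding convention."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)
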