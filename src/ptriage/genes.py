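"""Transcript models and coordinate arithmetic.

A :class:`TranscriptModel` stores exon and CDS geometry as 1-based inclusive
genomic intervals (ascending genomic order internally).  All queries that
depend on reading direction (coding-exon rank, distance to a junction,
fraction of the protein removed) are expressed in transcript orientation,
i.e. 5'->3' on the coding strand.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or codon not in CODON_TABLE:
        raise ValueError(f"not a codon: {codon!r}")
    return CODON_TABLE[codon]


@dataclass
class TranscriptModel:
    """Exon/CDS geometry of one transcript.

    ``exons`` and ``cds`` are lists of 1-based inclusive ``(start, end)``
    genomic intervals; they are stored sorted in ascending genomic order and
    must be non-overlapping.  ``alt_start_cds_offset`` carries an annotated
    in-frame downstream translation start (1-based CDS offset) when one
    exists within the first coding exon.
    """

    transcript_id: str
    gene: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    mane_select: bool = False
    noncoding_likely: bool = False
    alt_start_cds_offset: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for ivs, label in ((self.exons, "exon"), (self.cds, "CDS")):
            for (a, b) in ivs:
                if a > b:
                    raise ValueError(f"inverted {label} interval ({a},{b})")
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 <= b1:
                    raise ValueError(f"overlapping {label} intervals")

    # -- basic geometry ---------------------------------------------------

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def coding_exons(self) -> list[tuple[int, int]]:
        """CDS intervals in transcript (5'->3') orientation."""
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def exons_tx_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def exon_containing(self, pos: int) -> tuple[int, int] | None:
        for a, b in self.exons:
            if a <= pos <= b:
                return (a, b)
        return None

    def exon_rank(self, exon: tuple[int, int]) -> int:
        """0-based rank of an exon in transcript orientation."""
        return self.exons_tx_order().index(tuple(exon))

    # -- CDS coordinate mapping -------------------------------------------

    def _cum_coding_lengths(self) -> list[int]:
        out, total = [], 0
        for a, b in self.coding_exons():
            total += b - a + 1
            out.append(total)
        return out

    def cds_offset_of(self, pos: int) -> int | None:
        """1-based CDS offset of a genomic position, None if non-coding."""
        offset = 0
        for a, b in self.coding_exons():
            if a <= pos <= b:
                within = (pos - a) if self.strand == "+" else (b - pos)
                return offset + within + 1
            offset += b - a + 1
        return None

    def genomic_of_cds_offset(self, cds_offset: int) -> int:
        if not 1 <= cds_offset <= self.cds_length:
            raise ValueError(
                f"CDS offset {cds_offset} outside 1..{self.cds_length}"
            )
        remaining = cds_offset
        for a, b in self.coding_exons():
            length = b - a + 1
            if remaining <= length:
                return a + remaining - 1 if self.strand == "+" else b - remaining + 1
            remaining -= length
        raise AssertionError("unreachable")

    def coding_exon_index(self, cds_offset: int) -> int:
        """0-based index (transcript orientation) of the coding exon holding
        the given CDS offset."""
        cum = self._cum_coding_lengths()
        if not 1 <= cds_offset <= cum[-1]:
            raise ValueError(f"CDS offset {cds_offset} outside CDS")
        return bisect_right(cum, cds_offset - 1)

    def distance_to_exon_3prime_junction(self, cds_offset: int) -> int:
        """Coding bp from the offset to the 3' end of its coding exon
        (0 when the offset is the junction-adjacent base)."""
        cum = self._cum_coding_lengths()
        idx = self.coding_exon_index(cds_offset)
        return cum[idx] - cds_offset

    def exon_coding_length(self, exon: tuple[int, int]) -> int:
        a, b = exon
        total = 0
        for ca, cb in self.cds:
            lo, hi = max(a, ca), min(b, cb)
            if lo <= hi:
                total += hi - lo + 1
        return total

    # -- sequence ----------------------------------------------------------

    def cds_sequence(self, contig_seq: str) -> str:
        """Spliced CDS sequence in transcript orientation (coding strand)."""
        parts = [contig_seq[a - 1 : b] for a, b in self.cds]
        seq = "".join(parts).upper()
        return seq if self.strand == "+" else reverse_complement(seq)

    def codon_at(self, contig_seq: str, codon_index: int) -> str:
        """Codon (coding strand) at 0-based codon index."""
        seq = self.cds_sequence(contig_seq)
        start = 3 * codon_index
        if start + 3 > len(seq):
            raise ValueError(f"codon index {codon_index} outside CDS")
        return seq[start : start + 3]

    # -- splice geometry ---------------------------------------------------

    def adjacent_exon_for_splice(self, pos: int, window: int = 2) -> tuple[int, int] | None:
        """The exon whose splice site a near-junction intronic variant hits.

        Essential splice variants sit within ``window`` bp of an exon edge,
        outside the exon itself; the affected exon is the nearest one.
        """
        best, best_d = None, None
        for a, b in self.exons:
            if a <= pos <= b:
                continue
            d = min(abs(pos - a), abs(pos - b))
            if d <= window and (best_d is None or d < best_d):
                best, best_d = (a, b), d
        return best
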