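"""Validated readers and writers for every external format the pipeline uses.

Formats: VCF 4.2 (pysam) with per-genotype ``GT:DP:GQ:AD`` plus a phase
partner field, GTF gene models (gffutils), FASTA (pyfaidx-compatible plain
text), and TSV tables (pandas) for samples, gene annotations, pext scores,
splice delta scores, ClinVar-like classifications, PSI matrices, genotype
dosages, and the synthetic truth table.

Every reader's output re-serialized through the matching writer and re-read
is identical; this round-trip property is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .genes import TranscriptModel
from .variants import (
    GenotypeCall,
    GeneInfo,
    PextTrack,
    Sample,
    SpliceAnnotation,
    TranscriptConsequence,
    VariantRecord,
    left_align,
    minimal_representation,
)

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# VCF

_VCF_INFO_FIELDS = [
    ("AC_EXOMES", "1", "Integer", "Alternate allele count, exome call set"),
    ("AN_EXOMES", "1", "Integer", "Allele number, exome call set"),
    ("AC_GENOMES", "1", "Integer", "Alternate allele count, genome call set"),
    ("AN_GENOMES", "1", "Integer", "Allele number, genome call set"),
    ("PASS_EXOMES", "1", "Integer", "QC pass flag in exomes (0/1)"),
    ("PASS_GENOMES", "1", "Integer", "QC pass flag in genomes (0/1)"),
    ("AC_GRP", ".", "String", "Per-ancestry-group allele counts (group:count)"),
    ("LOFTEE", "1", "String", "LOFTEE confidence (HC/LC/NA)"),
    ("CLINVAR", "1", "String", "Aggregate ClinVar classification (underscored)"),
    ("CSQ", ".", "String", "Consequences: transcript|gene|class|cds_offset"),
]

_GT_CODE = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1), "missing": (None, None)}


def _build_vcf_header(
    contigs: dict[str, int], sample_ids: list[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for fid, num, typ, desc in _VCF_INFO_FIELDS:
        header.info.add(fid, num, typ, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.formats.add("GQ", "1", "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("PHP", "1", "String", "Phase partner variant id, if known in cis")
    for s in sample_ids:
        header.add_sample(s)
    return header


def write_vcf(
    path: str | Path,
    variants: list[VariantRecord],
    genotypes: dict[str, dict[str, GenotypeCall]],
    sample_ids: list[str],
    contigs: dict[str, int],
) -> None:
    """Write a plain-text multi-sample VCF (sorted by contig then position)."""
    header = _build_vcf_header(contigs, sample_ids)
    order = {c: i for i, c in enumerate(contigs)}
    variants = sorted(variants, key=lambda v: (order[v.contig], v.pos, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                id=v.variant_id,
            )
            rec.filter.add("PASS")
            info = rec.info
            for key, val in (
                ("AC_EXOMES", v.ac_exomes),
                ("AN_EXOMES", v.an_exomes),
                ("AC_GENOMES", v.ac_genomes),
                ("AN_GENOMES", v.an_genomes),
            ):
                if val is not None:
                    info[key] = val
            if v.pass_exomes is not None:
                info["PASS_EXOMES"] = int(v.pass_exomes)
            if v.pass_genomes is not None:
                info["PASS_GENOMES"] = int(v.pass_genomes)
            if v.ac_by_ancestry:
                info["AC_GRP"] = tuple(
                    f"{g}:{c}" for g, c in sorted(v.ac_by_ancestry.items())
                )
            if v.loftee != "NA":
                info["LOFTEE"] = v.loftee
            if v.clinvar_class is not None:
                info["CLINVAR"] = v.clinvar_class.replace(" ", "_")
            if v.consequences:
                info["CSQ"] = tuple(
                    f"{c.transcript_id}|{c.gene}|{c.consequence}|"
                    f"{'' if c.cds_offset is None else c.cds_offset}"
                    for c in v.consequences
                )
            calls = genotypes.get(v.variant_id, {})
            for s in sample_ids:
                call = calls.get(s)
                fmt = rec.samples[s]
                if call is None:
                    fmt["GT"] = (0, 0)
                    continue
                fmt["GT"] = _GT_CODE[call.gt]
                if call.dp is not None:
                    fmt["DP"] = call.dp
                if call.gq is not None:
                    fmt["GQ"] = call.gq
                if call.ad_ref is not None and call.ad_alt is not None:
                    fmt["AD"] = (call.ad_ref, call.ad_alt)
                if call.phase_partner is not None:
                    fmt["PHP"] = call.phase_partner
            out.write(rec)



def _info_get(info, key, default=None):
    """pysam raises on INFO keys absent from the header; treat as missing."""
    try:
        return info[key]
    except KeyError:
        return default


def _decode_gt(gt: tuple | None, allele_index: int) -> str:
    if gt is None or all(a is None for a in gt):
        return "missing"
    n_alt = sum(1 for a in gt if a == allele_index)
    if n_alt == 0:
        return "hom_ref"
    if n_alt == len([a for a in gt if a is not None]):
        return "hom_alt"
    return "het"


def read_vcf(
    path: str | Path, reference: dict[str, str] | None = None
) -> tuple[list[VariantRecord], dict[str, dict[str, GenotypeCall]], list[str]]:
    """Read a VCF into records and a genotype matrix.

    Multi-allelic sites are decomposed to one record per alternate allele and
    alleles are normalized (minimal representation, left-aligned when a
    reference is supplied).
    """
    variants: list[VariantRecord] = []
    genotypes: dict[str, dict[str, GenotypeCall]] = {}
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                pos, ref_a, alt_a = rec.pos, rec.ref, alt
                if reference is not None and rec.contig in reference:
                    pos, ref_a, alt_a = left_align(
                        pos, ref_a, alt_a, reference[rec.contig]
                    )
                else:
                    pos, ref_a, alt_a = minimal_representation(pos, ref_a, alt_a)
                info = rec.info
                csq = []
                for entry in _info_get(info, "CSQ", ()) or ():
                    tx, gene, cls, off = entry.split("|")
                    csq.append(
                        TranscriptConsequence(
                            transcript_id=tx,
                            gene=gene,
                            consequence=cls,
                            cds_offset=int(off) if off else None,
                        )
                    )
                grp = {}
                for entry in _info_get(info, "AC_GRP", ()) or ():
                    g, c = entry.rsplit(":", 1)
                    grp[g] = int(c)
                clin = _info_get(info, "CLINVAR")
                v = VariantRecord(
                    contig=rec.contig,
                    pos=pos,
                    ref=ref_a,
                    alt=alt_a,
                    ac_exomes=_info_get(info, "AC_EXOMES"),
                    an_exomes=_info_get(info, "AN_EXOMES"),
                    ac_genomes=_info_get(info, "AC_GENOMES"),
                    an_genomes=_info_get(info, "AN_GENOMES"),
                    pass_exomes=(
                        None if _info_get(info, "PASS_EXOMES") is None
                        else bool(_info_get(info, "PASS_EXOMES"))
                    ),
                    pass_genomes=(
                        None if _info_get(info, "PASS_GENOMES") is None
                        else bool(_info_get(info, "PASS_GENOMES"))
                    ),
                    ac_by_ancestry=grp,
                    consequences=csq,
                    loftee=_info_get(info, "LOFTEE") or "NA",
                    clinvar_class=(
                        None if clin is None else clin.replace("_", " ")
                    ),
                )
                variants.append(v)
                vid = v.variant_id
                calls: dict[str, GenotypeCall] = {}
                for s in sample_ids:
                    fmt = rec.samples[s]
                    ad = fmt.get("AD")
                    pp = fmt.get("PHP")
                    # htslib encodes a missing string value as \x07 fill bytes
                    if pp is not None and (not pp or set(pp) <= {".", "\x07"}):
                        pp = None
                    calls[s] = GenotypeCall(
                        sample_id=s,
                        variant_id=vid,
                        gt=_decode_gt(fmt.get("GT"), ai),
                        dp=fmt.get("DP"),
                        gq=fmt.get("GQ"),
                        ad_ref=None if ad is None else ad[0],
                        ad_alt=None if ad is None else ad[ai],
                        phase_partner=pp,
                    )
                genotypes[vid] = calls
    return variants, genotypes, sample_ids


# ---------------------------------------------------------------------------
# GTF


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    lines = []
    for t in sorted(transcripts, key=lambda t: (t.contig, t.exons[0][0], t.transcript_id)):
        attrs = f'gene_id "{t.gene}"; transcript_id "{t.transcript_id}";'
        if t.mane_select:
            attrs += ' tag "MANE_Select";'
        if t.noncoding_likely:
            attrs += ' tag "noncoding_likely";'
        if t.alt_start_cds_offset is not None:
            attrs += f' alt_start_cds_offset "{t.alt_start_cds_offset}";'
        span = (t.exons[0][0], t.exons[-1][1])
        lines.append(
            "\t".join(
                [t.contig, "ptriage", "transcript", str(span[0]), str(span[1]),
                 ".", t.strand, ".", attrs]
            )
        )
        for a, b in t.exons:
            lines.append(
                "\t".join(
                    [t.contig, "ptriage", "exon", str(a), str(b), ".",
                     t.strand, ".", attrs]
                )
            )
        for a, b in t.cds:
            lines.append(
                "\t".join(
                    [t.contig, "ptriage", "CDS", str(a), str(b), ".",
                     t.strand, "0", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> dict[str, TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        tid = feat.attributes["transcript_id"][0]
        info = meta.setdefault(
            tid,
            {
                "gene": feat.attributes["gene_id"][0],
                "contig": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
                "tags": set(),
                "alt_start": None,
            },
        )
        tags = feat.attributes.get("tag", [])
        info["tags"].update(tags)
        if "alt_start_cds_offset" in feat.attributes:
            info["alt_start"] = int(feat.attributes["alt_start_cds_offset"][0])
        if feat.featuretype == "exon":
            info["exons"].append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            info["cds"].append((feat.start, feat.end))
    out = {}
    for tid, info in meta.items():
        out[tid] = TranscriptModel(
            transcript_id=tid,
            gene=info["gene"],
            contig=info["contig"],
            strand=info["strand"],
            exons=info["exons"],
            cds=info["cds"],
            mane_select="MANE_Select" in info["tags"],
            noncoding_likely="noncoding_likely" in info["tags"],
            alt_start_cds_offset=info["alt_start"],
        )
    return out


# ---------------------------------------------------------------------------
# TSV tables


def write_samples(samples: list[Sample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "ancestry_group": [s.ancestry_group for s in samples],
            "project": [s.project for s in samples],
            "age": [s.age for s in samples],
            "data_type": [s.data_type for s in samples],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.1f")


def read_samples(path: str | Path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out = []
    for row in df.itertuples(index=False):
        age = None if pd.isna(row.age) else float(row.age)
        out.append(
            Sample(
                sample_id=row.sample_id,
                ancestry_group=row.ancestry_group,
                project=row.project,
                age=age,
                data_type=row.data_type,
            )
        )
    return out


def write_gene_info(genes: list[GeneInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [g.gene for g in genes],
            "omim_patterns": [",".join(sorted(g.omim_patterns)) for g in genes],
            "pli": [g.pli for g in genes],
            "loeuf": [g.loeuf for g in genes],
            "is_ch_gene": [int(g.is_ch_gene) for g in genes],
            "in_panel": [int(g.in_panel) for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_info(path: str | Path) -> dict[str, GeneInfo]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        patterns = (
            frozenset()
            if pd.isna(row.omim_patterns) or row.omim_patterns == ""
            else frozenset(str(row.omim_patterns).split(","))
        )
        out[row.gene] = GeneInfo(
            gene=row.gene,
            omim_patterns=patterns,
            pli=None if pd.isna(row.pli) else float(row.pli),
            loeuf=None if pd.isna(row.loeuf) else float(row.loeuf),
            is_ch_gene=bool(row.is_ch_gene),
            in_panel=bool(row.in_panel),
        )
    return out


def write_pext(tracks: dict[str, PextTrack], contigs: dict[str, str], path: str | Path) -> None:
    """``contigs`` maps gene -> contig name (pext intervals are genomic)."""
    rows = []
    for gene, track in sorted(tracks.items()):
        for (a, b), score in sorted(track.exon_scores.items()):
            rows.append((gene, contigs[gene], a, b, score))
    pd.DataFrame(
        rows, columns=["gene", "contig", "start", "end", "mean_pext"]
    ).to_csv(path, sep="\t", index=False)


def read_pext(path: str | Path) -> tuple[dict[str, PextTrack], dict[str, str]]:
    df = pd.read_csv(path, sep="\t")
    tracks: dict[str, PextTrack] = {}
    contigs: dict[str, str] = {}
    for row in df.itertuples(index=False):
        track = tracks.setdefault(row.gene, PextTrack(gene=row.gene))
        track.exon_scores[(int(row.start), int(row.end))] = float(row.mean_pext)
        contigs[row.gene] = row.contig
    return tracks, contigs


_SPLICE_COLS = [
    "acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss",
    "acceptor_gain_pos", "acceptor_loss_pos", "donor_gain_pos", "donor_loss_pos",
]


def write_splice(annots: dict[str, SpliceAnnotation], path: str | Path) -> None:
    rows = []
    for vid, a in sorted(annots.items()):
        rows.append([vid] + [getattr(a, c) for c in _SPLICE_COLS])
    pd.DataFrame(rows, columns=["variant_id"] + _SPLICE_COLS).to_csv(
        path, sep="\t", index=False
    )


def read_splice(path: str | Path) -> dict[str, SpliceAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        kwargs = {c: getattr(row, c) for c in _SPLICE_COLS}
        for c in _SPLICE_COLS[4:]:
            kwargs[c] = int(kwargs[c])
        out[row.variant_id] = SpliceAnnotation(variant_id=row.variant_id, **kwargs)
    return out


def write_clinvar(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clinvar(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, float_format="%.6g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# Cohort bundle


COHORT_FILES = {
    "reference": "reference.fa",
    "vcf": "cohort.vcf",
    "samples": "samples.tsv",
    "gtf": "genes.gtf",
    "gene_info": "gene_info.tsv",
    "pext": "pext.tsv",
    "splice": "splice_scores.tsv",
    "clinvar": "clinvar.tsv",
    "psi": "psi.tsv",
    "dosages": "dosages.tsv",
    "truth": "truth.tsv",
}


@dataclass
class Cohort:
    """In-memory bundle of every input the pipeline stages consume."""

    reference: dict[str, str]
    variants: list[VariantRecord]
    genotypes: dict[str, dict[str, GenotypeCall]]
    sample_ids: list[str]
    samples: list[Sample]
    transcripts: dict[str, TranscriptModel]
    gene_info: dict[str, GeneInfo]
    pext: dict[str, PextTrack]
    splice: dict[str, SpliceAnnotation]
    clinvar: pd.DataFrame
    psi: pd.DataFrame = field(default_factory=pd.DataFrame)
    dosages: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples_by_id(self) -> dict[str, Sample]:
        return {s.sample_id: s for s in self.samples}

    def variants_by_id(self) -> dict[str, VariantRecord]:
        return {v.variant_id: v for v in self.variants}

    def transcripts_of_gene(self, gene: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene == gene]


def load_cohort(directory: str | Path) -> Cohort:
    d = Path(directory)
    reference = read_fasta(d / COHORT_FILES["reference"])
    variants, genotypes, sample_ids = read_vcf(
        d / COHORT_FILES["vcf"], reference=reference
    )
    samples = read_samples(d / COHORT_FILES["samples"])
    transcripts = read_gtf(d / COHORT_FILES["gtf"])
    gene_info = read_gene_info(d / COHORT_FILES["gene_info"])
    pext, _ = read_pext(d / COHORT_FILES["pext"])
    splice = read_splice(d / COHORT_FILES["splice"])
    clinvar = read_clinvar(d / COHORT_FILES["clinvar"])
    psi_path = d / COHORT_FILES["psi"]
    psi = read_matrix(psi_path) if psi_path.exists() else pd.DataFrame()
    dos_path = d / COHORT_FILES["dosages"]
    dosages = read_matrix(dos_path) if dos_path.exists() else pd.DataFrame()
    truth_path = d / COHORT_FILES["truth"]
    truth = read_truth(truth_path) if truth_path.exists() else pd.DataFrame()
    return Cohort(
        reference=reference,
        variants=variants,
        genotypes=genotypes,
        sample_ids=sample_ids,
        samples=samples,
        transcripts=transcripts,
        gene_info=gene_info,
        pext=pext,
        splice=splice,
        clinvar=clinvar,
        psi=psi,
        dosages=dosages,
        truth=truth,
    )
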