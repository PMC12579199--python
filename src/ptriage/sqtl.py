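"""Splicing-QTL association and exon-overlap flagging.

Tests each exon's inclusion level (PSI) against genotype dosages of variants
within a cis window using rank-based (Spearman) association, controls the
false discovery rate with Benjamini-Hochberg across all tested pairs, and
flags pLoF variants that fall inside exons whose inclusion is modulated by
a significant sQTL — alternative splicing of the region being a candidate
mechanism of incomplete penetrance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .variants import (
    GenotypeCall,
    PextTrack,
    VariantRecord,
    parse_variant_id,
)


@dataclass
class SqtlHit:
    exon_id: str
    contig: str
    exon_start: int
    exon_end: int
    variant_id: str
    statistic: float  # Spearman rho
    p: float
    q: float
    direction: str  # increases_inclusion | decreases_inclusion

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.exon_start <= pos <= self.exon_end


def parse_exon_id(exon_id: str) -> tuple[str, int, int]:
    contig, span = exon_id.split(":")
    a, b = span.split("-")
    return contig, int(a), int(b)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fit_exon_sqtl(
    psi: pd.DataFrame,
    dosages: pd.DataFrame,
    window_bp: int = 1_000_000,
    fdr: float = 0.05,
    min_samples: int = 10,
) -> tuple[list[SqtlHit], pd.DataFrame]:
    """Associate exon inclusion with cis genotype dosages.

    ``psi``: exon_id x sample matrix of inclusion fractions; ``dosages``:
    variant_id x sample matrix of alternate-allele dosages (0/1/2).  Pairs
    are tested when the variant lies within ``window_bp`` of the exon and at
    least ``min_samples`` samples have both values; constant PSI or dosage
    vectors are skipped.  Returns the hits at q < ``fdr`` plus the full
    tested-pair table.
    """
    shared = [s for s in psi.columns if s in dosages.columns]
    rows = []
    for exon_id in psi.index:
        contig, a, b = parse_exon_id(exon_id)
        y_all = psi.loc[exon_id, shared].to_numpy(dtype=float)
        for vid in dosages.index:
            vc, pos, _, _ = parse_variant_id(vid)
            if vc != contig:
                continue
            if pos < a - window_bp or pos > b + window_bp:
                continue
            x_all = dosages.loc[vid, shared].to_numpy(dtype=float)
            mask = ~(np.isnan(x_all) | np.isnan(y_all))
            if mask.sum() < min_samples:
                continue
            x, y = x_all[mask], y_all[mask]
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue  # constant vector: uninformative pair
            rho, p = spearmanr(x, y)
            rows.append(
                {
                    "exon_id": exon_id,
                    "variant_id": vid,
                    "rho": float(rho),
                    "p": float(p),
                    "n": int(mask.sum()),
                }
            )
    table = pd.DataFrame(rows, columns=["exon_id", "variant_id", "rho", "p", "n"])
    if table.empty:
        table["q"] = []
        return [], table
    table["q"] = bh_adjust(table["p"].to_numpy())
    hits = []
    for row in table.itertuples(index=False):
        if row.q < fdr:
            contig, a, b = parse_exon_id(row.exon_id)
            hits.append(
                SqtlHit(
                    exon_id=row.exon_id,
                    contig=contig,
                    exon_start=a,
                    exon_end=b,
                    variant_id=row.variant_id,
                    statistic=row.rho,
                    p=row.p,
                    q=row.q,
                    direction=(
                        "increases_inclusion" if row.rho > 0
                        else "decreases_inclusion"
                    ),
                )
            )
    hits.sort(key=lambda h: h.q)
    return hits, table


@dataclass
class SqtlFlag:
    variant_id: str
    sqtl_variant_id: str
    exon_id: str
    q: float
    carrier_genotypes: dict[str, str] = field(default_factory=dict)
    pext_concordant: bool = False


def flag_sqtl_overlap(
    plof_variants: list[VariantRecord],
    hits: list[SqtlHit],
    pext: dict[str, PextTrack],
    genotypes: dict[str, dict[str, GenotypeCall]],
    pext_reduced_max: float = 0.5,
) -> dict[str, SqtlFlag]:
    """Flag pLoF variants inside sQTL-responsive exons.

    For each flagged variant the carriers' genotype at the sQTL variant is
    reported, and co-reduction of the exon's relative pext score
    (<= ``pext_reduced_max`` of the gene maximum) is annotated.
    """
    flags: dict[str, SqtlFlag] = {}
    for v in plof_variants:
        hit = next(
            (h for h in hits if h.contains(v.contig, v.pos)), None
        )
        if hit is None:
            continue
        carriers = [
            sid
            for sid, c in genotypes.get(v.variant_id, {}).items()
            if c.is_carrier
        ]
        sqtl_calls = genotypes.get(hit.variant_id, {})
        carrier_gts = {
            sid: (sqtl_calls[sid].gt if sid in sqtl_calls else "missing")
            for sid in carriers
        }
        gene = v.consequences[0].gene if v.consequences else None
        track = pext.get(gene) if gene else None
        rel = track.relative_score_at(v.pos) if track else None
        flags[v.variant_id] = SqtlFlag(
            variant_id=v.variant_id,
            sqtl_variant_id=hit.variant_id,
            exon_id=hit.exon_id,
            q=hit.q,
            carrier_genotypes=carrier_gts,
            pext_concordant=rel is not None and rel <= pext_reduced_max,
        )
    return flags
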