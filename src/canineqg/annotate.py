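"""Map significant SNPs to candidate genes within a symmetric window.

A SNP passing the p-value threshold is linked to every gene whose span
intersects the closed interval [pos - window, pos + window]; the distance
is 0 when the SNP lies inside the gene, otherwise the gap to the nearest
gene edge. Gene coordinates come from a user-supplied table (1-based
inclusive; see :func:`canineqg.formats.read_gene_bed`).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SnpGeneHit", "window_genes", "hits_to_frame"]


@dataclass(frozen=True)
class SnpGeneHit:
    snp_id: str
    chromosome: str
    position_bp: int
    p_value: float
    gene_id: str
    gene_name: str
    gene_start_bp: int
    gene_end_bp: int
    distance_bp: int
    relation: str  # within / upstream / downstream (gene relative to SNP)


def window_genes(
    gwas,
    genes: pd.DataFrame,
    threshold_p: float,
    window_bp: int = 500_000,
) -> list[SnpGeneHit]:
    """All SNP-gene pairs within +-``window_bp`` for significant SNPs.

    ``gwas`` is a :class:`canineqg.gwas.GwasTable` or its per-SNP DataFrame;
    ``genes`` a gene table with 1-based inclusive spans. Window edges are
    inclusive (closed intervals). Results are sorted by chromosome,
    position, then distance.
    """
    snps = gwas.snps if hasattr(gwas, "snps") else gwas
    sig = snps.loc[snps["p_wald"] <= threshold_p]
    hits: list[SnpGeneHit] = []
    if sig.empty or genes.empty:
        return hits
    by_chrom = {c: g for c, g in genes.groupby("chromosome")}
    for row in sig.itertuples(index=False):
        chrom = str(row.chromosome)
        g = by_chrom.get(chrom)
        if g is None:
            continue
        pos = int(row.position_bp)
        start = g["start_bp"].to_numpy()
        end = g["end_bp"].to_numpy()
        near = (start <= pos + window_bp) & (end >= pos - window_bp)
        for k in np.flatnonzero(near):
            s, e = int(start[k]), int(end[k])
            if s <= pos <= e:
                distance, relation = 0, "within"
            elif pos < s:  # gene lies downstream of the SNP position
                distance, relation = s - pos, "downstream"
            else:
                distance, relation = pos - e, "upstream"
            hits.append(
                SnpGeneHit(
                    snp_id=str(row.snp_id),
                    chromosome=chrom,
                    position_bp=pos,
                    p_value=float(row.p_wald),
                    gene_id=str(g["gene_id"].iloc[k]),
                    gene_name=str(g["name"].iloc[k]),
                    gene_start_bp=s,
                    gene_end_bp=e,
                    distance_bp=distance,
                    relation=relation,
                )
            )
    hits.sort(key=lambda h: (h.chromosome, h.position_bp, h.distance_bp, h.gene_id))
    return hits


def hits_to_frame(hits: list[SnpGeneHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])
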