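"""QTL-gene containment statistics.

A gene *hits* a QTL when its genomic interval is completely contained in the
QTL interval on the same chromosome (closed 1-based coordinates on both
sides):

    hit(g, q) = 1  iff  g.chrom == q.chrom and q.start <= g.start
                        and g.stop <= q.stop

``NQhits`` is the number of *distinct* genes of a gene set G with at least
one hit; a gene inside several overlapping QTLs counts once, which keeps the
hit proportion Pr_GQ = NQhits / n inside [0, 1].  The raw double sum over all
(gene, QTL) pairs — which multi-counts such genes — is reported separately as
``nqhits_multicount`` for diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from .genome_io import Gene, GeneSet, GeneSpace, Qtl, QtlSet

logger = logging.getLogger(__name__)

__all__ = [
    "qtl_hit",
    "genome_hits",
    "hit_profile",
    "candidate_genes",
    "chromosome_distribution",
    "qtl_distribution",
    "HitProfile",
]


@dataclass(frozen=True)
class HitProfile:
    """Hit counts and proportions for a gene set G against Q.

    Attributes
    ----------
    nqhits : distinct genes of G contained in >= 1 QTL
    n : size of G
    pr_gq : nqhits / n
    nqhits_complement : distinct hit genes in G' = Omega - G
    pr_gq_complement : nqhits_complement / (N - n); NaN when n = N
    hit_gene_ids : the hit genes of G, in gene-set order
    nqhits_multicount : raw double sum over (gene, QTL) pairs in G
    """

    nqhits: int
    n: int
    pr_gq: float
    nqhits_complement: int
    pr_gq_complement: float
    hit_gene_ids: tuple[str, ...]
    nqhits_multicount: int

    def to_dict(self) -> dict:
        return {
            "nqhits": self.nqhits,
            "n": self.n,
            "pr_gq": self.pr_gq,
            "nqhits_complement": self.nqhits_complement,
            "pr_gq_complement": self.pr_gq_complement,
            "hit_gene_ids": list(self.hit_gene_ids),
            "nqhits_multicount": self.nqhits_multicount,
        }


def qtl_hit(gene: Gene, qtl: Qtl) -> int:
    """Containment indicator: 1 iff the gene lies completely inside the QTL."""
    return int(
        gene.chrom == qtl.chrom
        and qtl.start <= gene.start
        and gene.stop <= qtl.stop
    )


def genome_hits(space: GeneSpace, qtls: QtlSet) -> np.ndarray:
    """Per-gene hit-count vector over the whole gene space.

    ``out[i]`` is the number of QTLs completely containing gene i (space
    order).  ``(out > 0).sum()`` is the genome-wide hit total N_Q; the raw sum
    is the multi-count diagnostic.  Vectorized per chromosome.
    """
    counts = np.zeros(space.N, dtype=np.int64)
    if len(qtls) == 0 or space.N == 0:
        return counts
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(space.genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    starts = np.array([g.start for g in space.genes], dtype=np.int64)
    stops = np.array([g.stop for g in space.genes], dtype=np.int64)
    for q in qtls:
        idx = by_chrom.get(q.chrom)
        if not idx:
            continue
        idx = np.asarray(idx)
        inside = (starts[idx] >= q.start) & (stops[idx] <= q.stop)
        counts[idx[inside]] += 1
    return counts


def _member_indices(gene_set: GeneSet, space: GeneSpace) -> np.ndarray:
    try:
        return np.array([space._index[g] for g in gene_set.member_ids])
    except KeyError as exc:
        raise ValidationError(f"gene set member {exc.args[0]!r} not in gene space") from exc


def hit_profile(gene_set: GeneSet, space: GeneSpace, qtls: QtlSet) -> HitProfile:
    """NQhits, hit proportions and complement quantities for a gene set."""
    if gene_set.n == 0:
        raise ValidationError("gene set is empty")
    counts = genome_hits(space, qtls)
    idx = _member_indices(gene_set, space)
    member_counts = counts[idx]
    hit_mask = member_counts > 0
    nqhits = int(hit_mask.sum())
    hit_ids = tuple(str(g) for g in np.asarray(gene_set.member_ids)[hit_mask])
    total_hits = int((counts > 0).sum())
    nqhits_c = total_hits - nqhits
    n, N = gene_set.n, space.N
    if n == N:
        logger.warning("gene set equals the whole gene space; Pr_G'Q is undefined")
        pr_c = math.nan
    else:
        pr_c = nqhits_c / (N - n)
    return HitProfile(
        nqhits=nqhits,
        n=n,
        pr_gq=nqhits / n,
        nqhits_complement=nqhits_c,
        pr_gq_complement=pr_c,
        hit_gene_ids=hit_ids,
        nqhits_multicount=int(member_counts.sum()),
    )


def candidate_genes(
    gene_set: GeneSet, space: GeneSpace, qtls: QtlSet
) -> dict[str, list[str]]:
    """QTL candidate genes: every hit gene of G mapped to *all* QTL ids that
    contain it, QTL ids in input order."""
    if gene_set.n == 0:
        raise ValidationError("gene set is empty")
    out: dict[str, list[str]] = {}
    for gid in gene_set.member_ids:
        g = space[gid]
        containing = [q.qtl_id for q in qtls if qtl_hit(g, q)]
        if containing:
            out[gid] = containing
    return out


def chromosome_distribution(gene_set: GeneSet, space: GeneSpace) -> dict[str, int]:
    """Gene-set member count per chromosome; chromosomes present in the space
    but empty in G are reported with count 0.  Counts sum to n."""
    dist = {c: 0 for c in space.chromosomes()}
    for gid in gene_set.member_ids:
        dist[space[gid].chrom] += 1
    return dist


def qtl_distribution(
    gene_set: GeneSet, space: GeneSpace, qtls: QtlSet
) -> dict[str, int]:
    """Contained-gene count per QTL.  A gene inside several QTLs contributes
    to each, so the column sum may exceed NQhits."""
    dist = {q.qtl_id: 0 for q in qtls}
    for gid in gene_set.member_ids:
        g = space[gid]
        for q in qtls:
            if qtl_hit(g, q):
                dist[q.qtl_id] += 1
    return dist
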