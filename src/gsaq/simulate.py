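"""Synthetic genomes, QTL maps, gene sets and expression matrices.

The generator emulates, at desk scale, the structure the enrichment test
consumes in practice: a multi-chromosome gene space with interval
coordinates, trait QTL intervals covering a sizeable fraction of the genome,
gene sets whose QTL-hit proportion is controllably inflated over background,
and a two-class log2 expression matrix with planted differentially expressed
genes, a configurable fraction of which lie inside QTL regions.

Defaults sketch a rice-like layout shrunk to desk scale: 12 chromosomes of
2 Mb carrying 5000 genes of 1-5 kb, and 60 QTLs of 50-150 kb (about 25% of
the genome covered before QTL-QTL overlap, so roughly a fifth of genes are
QTL-hit).  Every output is bit-reproducible from (config, seed).

``enrichment_ratio`` (rho) is the relative odds that a selected gene is a
QTL-hit gene: gene sets are drawn by weighted sampling without replacement
with weight rho on hit genes and 1 on the rest.  rho = 1 is the exact
competitive null (a uniform random set); rho -> infinity picks hit genes
first.  Weighted SRSWOR is realized with exponential/Gumbel sort keys
(Efraimidis-Spirakis), which is equivalent to sequential draws with weight
renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ValidationError
from .genome_io import ExpressionMatrix, Gene, GeneSet, GeneSpace, Qtl, QtlSet
from .overlap import genome_hits

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_qtls",
    "simulate_geneset",
    "simulate_expression",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic genome / QTL / expression generator."""

    n_genes: int = 5000
    n_chroms: int = 12
    chrom_length: int = 2_000_000
    gene_length: tuple[int, int] = (1_000, 5_000)
    n_qtls: int = 60
    qtl_length: tuple[int, int] = (50_000, 150_000)
    trait: str = "synthetic-trait"
    enrichment_ratio: float = 1.0
    # expression block
    n_case: int = 10
    n_control: int = 10
    effect_size: float = 2.0       # shift of DE genes in cases, in sd units
    n_de: int = 100                # planted differentially expressed genes
    frac_de_in_qtl: float = 0.5    # fraction of DE genes drawn from QTL-hit genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValidationError("need >= 1 gene and >= 1 chromosome")
        for lo, hi, what in (
            (*self.gene_length, "gene_length"),
            (*self.qtl_length, "qtl_length"),
        ):
            if not (0 < lo <= hi):
                raise ValidationError(f"{what} bounds must satisfy 0 < lo <= hi")
            if hi > self.chrom_length:
                raise ValidationError(f"{what} upper bound exceeds chromosome length")
        if self.enrichment_ratio < 1:
            raise ValidationError("enrichment_ratio must be >= 1")
        if self.n_qtls < 0:
            raise ValidationError("n_qtls must be >= 0")
        if not (0.0 <= self.frac_de_in_qtl <= 1.0):
            raise ValidationError("frac_de_in_qtl must lie in [0, 1]")


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _place_intervals(
    rng: np.random.Generator, n: int, n_chroms: int, chrom_length: int,
    length_lo: int, length_hi: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform random chromosome, length and start; intervals fit [1, L]."""
    chroms = rng.integers(0, n_chroms, size=n)
    lengths = rng.integers(length_lo, length_hi + 1, size=n)
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        starts[i] = rng.integers(1, chrom_length - lengths[i] + 2)
    return chroms, starts, starts + lengths - 1


def simulate_genome(cfg: SimConfig) -> GeneSpace:
    """Place genes uniformly at random; overlap between genes is allowed."""
    rng = np.random.default_rng(cfg.seed)
    names = _chrom_names(cfg.n_chroms)
    chroms, starts, stops = _place_intervals(
        rng, cfg.n_genes, cfg.n_chroms, cfg.chrom_length, *cfg.gene_length
    )
    width = len(str(cfg.n_genes))
    genes = [
        Gene(f"g{(i + 1):0{width}d}", names[chroms[i]], int(starts[i]), int(stops[i]))
        for i in range(cfg.n_genes)
    ]
    return GeneSpace(genes)


def simulate_qtls(cfg: SimConfig, space: GeneSpace | None = None) -> QtlSet:
    """Place QTL intervals uniformly at random.

    Uses a seed stream distinct from the genome's so genes and QTLs are
    independent given the config.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    names = _chrom_names(cfg.n_chroms)
    chroms, starts, stops = _place_intervals(
        rng, cfg.n_qtls, cfg.n_chroms, cfg.chrom_length, *cfg.qtl_length
    )
    width = max(3, len(str(max(cfg.n_qtls, 1))))
    qtls = [
        Qtl(f"AQ{(i + 1):0{width}d}", cfg.trait, names[chroms[i]],
            int(starts[i]), int(stops[i]))
        for i in range(cfg.n_qtls)
    ]
    return QtlSet(qtls, trait=cfg.trait)


def simulate_geneset(
    space: GeneSpace,
    qtls: QtlSet,
    n: int,
    rho: float = 1.0,
    seed: int = 0,
) -> GeneSet:
    """Draw a gene set of size n with hit genes favoured by odds rho >= 1.

    Weighted SRSWOR via exponential sort keys: gene i gets key
    Exp(1)/w_i and the n smallest keys win; w_i = rho for QTL-hit genes and
    1 otherwise.  rho = 1 reduces to uniform SRSWOR (competitive null).
    """
    if n > space.N:
        raise ValidationError(f"gene set size {n} exceeds gene space N={space.N}")
    if n < 1:
        raise ValidationError("gene set size must be >= 1")
    if rho < 1:
        raise ValidationError("rho must be >= 1")
    rng = np.random.default_rng(seed)
    hit = genome_hits(space, qtls) > 0
    w = np.where(hit, rho, 1.0)
    keys = rng.exponential(size=space.N) / w
    chosen = np.argsort(keys, kind="stable")[:n]
    chosen.sort()  # stable, space-order membership listing
    ids = np.asarray(space.gene_ids)
    return GeneSet((str(g) for g in ids[chosen]), space)


def simulate_expression(
    space: GeneSpace, qtls: QtlSet, cfg: SimConfig
) -> tuple[ExpressionMatrix, dict]:
    """Two-class log2 expression with planted DE genes.

    Background is N(0, 1) per gene and sample; planted DE genes are shifted
    by ``cfg.effect_size`` standard deviations in cases.  A fraction
    ``cfg.frac_de_in_qtl`` of the planted genes is drawn from QTL-hit genes,
    the rest from non-hit genes, linking expression-based selection to the
    enrichment test end to end.

    Returns the matrix and a truth record with keys ``de_gene_ids``,
    ``de_in_qtl_ids`` and ``de_outside_qtl_ids``.
    """
    if cfg.n_case < 2 or cfg.n_control < 2:
        raise ValidationError("need >= 2 case and >= 2 control samples")
    if cfg.n_de > space.N:
        raise ValidationError("more DE genes requested than genes in the space")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    hit = genome_hits(space, qtls) > 0
    ids = np.asarray(space.gene_ids)
    n_in = int(round(cfg.frac_de_in_qtl * cfg.n_de))
    n_out = cfg.n_de - n_in
    hit_pool, nonhit_pool = ids[hit], ids[~hit]
    if n_in > hit_pool.size:
        raise ValidationError(
            f"requested {n_in} DE genes inside QTL regions but only "
            f"{hit_pool.size} hit genes exist"
        )
    if n_out > nonhit_pool.size:
        raise ValidationError(
            f"requested {n_out} DE genes outside QTL regions but only "
            f"{nonhit_pool.size} non-hit genes exist"
        )
    de_in = [str(g) for g in rng.choice(hit_pool, size=n_in, replace=False)]
    de_out = [str(g) for g in rng.choice(nonhit_pool, size=n_out, replace=False)]
    de_ids = de_in + de_out
    de_idx = np.array([space._index[g] for g in de_ids], dtype=int)

    n_samples = cfg.n_control + cfg.n_case
    values = rng.normal(size=(space.N, n_samples))
    case_cols = np.arange(cfg.n_control, n_samples)
    if len(de_idx):
        values[np.ix_(de_idx, case_cols)] += cfg.effect_size

    sample_ids = tuple(
        [f"ctrl{i + 1:02d}" for i in range(cfg.n_control)]
        + [f"case{i + 1:02d}" for i in range(cfg.n_case)]
    )
    labels = ("control",) * cfg.n_control + ("case",) * cfg.n_case
    expr = ExpressionMatrix(tuple(ids), sample_ids, labels, values)
    truth = {
        "de_gene_ids": de_ids,
        "de_in_qtl_ids": de_in,
        "de_outside_qtl_ids": de_out,
    }
    return expr, truth
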