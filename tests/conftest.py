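import numpy as np
import pytest

from gsaq import Gene, GeneSet, GeneSpace, Qtl, QtlSet


@pytest.fixture
def toy_space():
    """Three genes on two chromosomes (the worked example used throughout)."""
    return GeneSpace(
        [
            Gene("gA", "chr1", 100, 200),
            Gene("gB", "chr1", 900, 950),
            Gene("gC", "chr2", 10, 20),
        ]
    )


@pytest.fixture
def toy_qtls():
    return QtlSet(
        [
            Qtl("q1", "salinity", "chr1", 50, 500),
            Qtl("q2", "salinity", "chr1", 60, 450),
        ]
    )


@pytest.fixture
def toy_set(toy_space):
    return GeneSet(["gA", "gB", "gC"], toy_space)


@pytest.fixture
def ten_gene_instance():
    """N=10 genes on one chromosome, one QTL containing exactly 4 of them,
    and a 5-gene set with 3 hits — so the single-shot test must return the
    enumeration value 66/252."""
    genes = [Gene(f"g{i}", "chr1", 1000 * i + 1, 1000 * i + 100) for i in range(1, 11)]
    space = GeneSpace(genes)
    # QTL spans genes g1..g4 completely, g5 onward not at all
    qtls = QtlSet([Qtl("q1", "trait", "chr1", 1, 4200)])
    gene_set = GeneSet(["g1", "g2", "g3", "g5", "g6"], space)  # 3 hits of 5
    return space, qtls, gene_set


def random_instance(rng, n_genes=50, n_chroms=3, chrom_len=100_000, n_qtls=8):
    """Small random gene space + QTL set for brute-force cross-checks."""
    genes = []
    for i in range(n_genes):
        c = rng.integers(0, n_chroms)
        length = int(rng.integers(50, 2_000))
        start = int(rng.integers(1, chrom_len - length + 1))
        genes.append(Gene(f"g{i:03d}", f"chr{c + 1}", start, start + length - 1))
    qtls = []
    for j in range(n_qtls):
        c = rng.integers(0, n_chroms)
        length = int(rng.integers(2_000, 40_000))
        start = int(rng.integers(1, chrom_len - length + 1))
        qtls.append(Qtl(f"q{j:02d}", "trait", f"chr{c + 1}", start, start + length - 1))
    return GeneSpace(genes), QtlSet(qtls)
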