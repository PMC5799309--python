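"""Competitive enrichment of a gene set with trait-specific QTLs.

The test asks whether genes of a selected set G are more often completely
contained in QTL intervals than genes of the complement G' = Omega - G
(competitive null hypothesis, one-sided alternative "more often").

Gene sampling model
-------------------
Genes — not subjects — are the sampling units.  K samples G_1..G_K, each of
size m <= n, are drawn from G by simple random sampling without replacement
(independently of one another).  For each sample a 2x2 table of
(in sample / not) x (QTL hit / not) is formed; under the null the sample's
hit count follows Hypergeometric(N, N_Q, m), where N_Q is the genome-wide
number of hit genes.  The per-sample upper-tail p-values p_1..p_K are then
combined into one statistic by one of four classical methods:

=================  =============================================  ===========
method             statistic                                      null dist.
=================  =============================================  ===========
inverse_normal     T = sum_k w_k Phi^-1(p_k),   w_k = 1/sqrt(K)   N(0, 1)
mean_p             W = (0.5 - pbar) * sqrt(12 K)                  N(0, 1)
inverse_chisq      L = sum_k -2 log p_k                           chi2_{2K}
logit              S = sum_k log(p_k / (1 - p_k)), scaled by C    t_{5K+4}
=================  =============================================  ===========

with C = sqrt(K pi^2 (5K+2) / (3 (5K+4))) so that S/C matches the stated t
reference distribution.  Direction conventions are fixed so that small
combined p means enrichment for every method.

The single-shot baseline (``gsvq_test``) applies the same hypergeometric
upper tail once to the whole set G with no resampling.

Caveat: the K samples are drawn from the same G, so the p_k are positively
correlated; the combination treats them as independent.  See the methods
note for the calibration consequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .genome_io import GeneSet, GeneSpace, QtlSet
from .overlap import genome_hits

__all__ = [
    "SamplingPlan",
    "ContingencyTable",
    "GsaqResult",
    "COMBINE_METHODS",
    "draw_gene_samples",
    "contingency_table",
    "hypergeom_upper_p",
    "sample_pvalues",
    "combine_pvalues",
    "gsaq_test",
    "gsvq_test",
    "fdr_adjust",
]

COMBINE_METHODS = ("inverse_normal", "mean_p", "inverse_chisq", "logit")

# hypergeometric p of exactly 1 (x = 0) is common; clamp before
# Phi^-1 / log / logit transforms so no combiner sees an infinity
P_EPS = 1e-10


@dataclass(frozen=True)
class SamplingPlan:
    """K gene samples of size m (<= n), seeded for reproducibility."""

    K: int
    m: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one gene sample: (in sample / complement) x (hit / not)."""

    n_gkq: int       # hit genes in G_k
    n_gkqc: int      # non-hit genes in G_k
    n_gkc_q: int     # hit genes in Omega - G_k
    n_gkc_qc: int    # non-hit genes in Omega - G_k

    def __post_init__(self) -> None:
        for cell in (self.n_gkq, self.n_gkqc, self.n_gkc_q, self.n_gkc_qc):
            if cell < 0:
                raise ValidationError("contingency table cell < 0")

    @property
    def m(self) -> int:
        return self.n_gkq + self.n_gkqc

    @property
    def N_Q(self) -> int:
        return self.n_gkq + self.n_gkc_q

    @property
    def N(self) -> int:
        return self.n_gkq + self.n_gkqc + self.n_gkc_q + self.n_gkc_qc


@dataclass(frozen=True)
class GsaqResult:
    """Everything needed to report and reproduce one GSAQ run."""

    sample_nqhits: tuple[int, ...]
    sample_pvalues: tuple[float, ...]
    method: str
    statistic: float
    df: int | None
    combined_p: float
    K: int
    m: int
    seed: int
    N: int
    N_Q: int
    n: int
    tail: str = "inclusive"
    weights: tuple[float, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "sample_index": list(range(1, self.K + 1)),
            "nqhits": list(self.sample_nqhits),
            "p_k": list(self.sample_pvalues),
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "combined_p": self.combined_p,
            "K": self.K,
            "m": self.m,
            "seed": self.seed,
            "N": self.N,
            "N_Q": self.N_Q,
            "n": self.n,
            "tail": self.tail,
            "weights": None if self.weights is None else list(self.weights),
        }


def draw_gene_samples(
    gene_set: GeneSet, plan: SamplingPlan, rng: np.random.Generator | None = None
) -> list[tuple[str, ...]]:
    """Draw K SRSWOR samples of m gene ids from G, independently per sample.

    Fully reproducible from ``plan.seed`` (or from a caller-provided ``rng``,
    in which case the seed in the plan is ignored).
    """
    if plan.m > gene_set.n:
        raise ValidationError(f"sample size m={plan.m} exceeds gene set n={gene_set.n}")
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    ids = np.asarray(gene_set.member_ids)
    return [tuple(rng.choice(ids, size=plan.m, replace=False)) for _ in range(plan.K)]


def contingency_table(
    sample_ids, space: GeneSpace, qtls: QtlSet, *, hit_counts: np.ndarray | None = None
) -> ContingencyTable:
    """Build the 2x2 table for one gene sample against the whole space.

    ``hit_counts`` may carry a precomputed :func:`~gsaq.overlap.genome_hits`
    vector to avoid rescanning the genome per sample.
    """
    if hit_counts is None:
        hit_counts = genome_hits(space, qtls)
    hit = hit_counts > 0
    idx = []
    for gid in sample_ids:
        if gid not in space:
            raise ValidationError(f"sample gene {gid!r} not in gene space")
        idx.append(space._index[gid])
    idx = np.asarray(idx, dtype=int)
    x = int(hit[idx].sum()) if len(idx) else 0
    m = len(idx)
    N_Q = int(hit.sum())
    N = space.N
    table = ContingencyTable(x, m - x, N_Q - x, (N - m) - (N_Q - x))
    assert table.m == m and table.N_Q == N_Q and table.N == N  # margin check
    return table


def hypergeom_upper_p(
    x: int, N: int, N_Q: int, m: int, tail: str = "inclusive"
) -> float:
    """Upper-tail hypergeometric p-value for observing x hits in a sample of m.

    ``tail='inclusive'`` returns P[X >= x] = 1 - P[X <= x-1] (the standard
    enrichment convention); ``tail='exclusive'`` returns P[X > x], the
    literal exceedance.  Result clamped to [0, 1].
    """
    if not (0 <= N_Q <= N):
        raise ValidationError(f"need 0 <= N_Q <= N, got N_Q={N_Q}, N={N}")
    if not (0 <= m <= N):
        raise ValidationError(f"need 0 <= m <= N, got m={m}, N={N}")
    if x < 0 or x > min(m, N_Q):
        raise ValidationError(
            f"impossible hit count x={x} for m={m}, N_Q={N_Q} (max {min(m, N_Q)})"
        )
    if tail == "inclusive":
        p = stats.hypergeom.sf(x - 1, N, N_Q, m)
    elif tail == "exclusive":
        p = stats.hypergeom.sf(x, N, N_Q, m)
    else:
        raise ValidationError(f"unknown tail convention {tail!r}")
    return float(min(1.0, max(0.0, p)))


def sample_pvalues(
    gene_set: GeneSet,
    space: GeneSpace,
    qtls: QtlSet,
    plan: SamplingPlan,
    tail: str = "inclusive",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample upper-tail p-values and hit counts for K SRSWOR samples.

    Returns ``(pvalues, nqhits)`` arrays of length K.  N_Q is computed once
    over the whole space.
    """
    counts = genome_hits(space, qtls)
    hit = counts > 0
    N, N_Q = space.N, int(hit.sum())
    member_idx = np.array([space._index[g] for g in gene_set.member_ids])
    member_hit = hit[member_idx]
    if plan.m > gene_set.n:
        raise ValidationError(f"sample size m={plan.m} exceeds gene set n={gene_set.n}")
    rng = np.random.default_rng(plan.seed)
    xs = np.empty(plan.K, dtype=int)
    for k in range(plan.K):
        pick = rng.choice(gene_set.n, size=plan.m, replace=False)
        xs[k] = int(member_hit[pick].sum())
    shift = 1 if tail == "inclusive" else 0
    if tail not in ("inclusive", "exclusive"):
        raise ValidationError(f"unknown tail convention {tail!r}")
    ps = stats.hypergeom.sf(xs - shift, N, N_Q, plan.m)
    return np.clip(ps, 0.0, 1.0), xs


def _logit_scale(K: int) -> float:
    # Mudholkar-George: S / C ~ t_{5K+4}; C matches Var(S) = K pi^2 / 3 to the
    # t variance (5K+4)/(5K+2)
    return math.sqrt(K * math.pi**2 * (5 * K + 2) / (3.0 * (5 * K + 4)))


def combine_pvalues(
    pvals, method: str, weights=None
) -> tuple[float, float]:
    """Combine K p-values into (statistic, combined p) by the named method.

    p-values are clamped to [1e-10, 1 - 1e-10] before any transform.  For
    ``inverse_normal`` the weights must satisfy ||w||_2 = 1 (default
    w_k = 1/sqrt(K), i.e. the unweighted Stouffer statistic).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot combine an empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    K = p.size
    p = np.clip(p, P_EPS, 1.0 - P_EPS)

    if method == "inverse_normal":
        if weights is None:
            w = np.full(K, 1.0 / math.sqrt(K))
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (K,):
                raise ValidationError(f"expected {K} weights, got shape {w.shape}")
            if abs(np.linalg.norm(w) - 1.0) > 1e-8:
                raise ValidationError("inverse_normal weights must have unit L2 norm")
        T = float(np.dot(w, stats.norm.ppf(p)))
        return T, float(stats.norm.cdf(T))
    if weights is not None:
        raise ValidationError(f"weights are only supported for inverse_normal, not {method!r}")
    if method == "mean_p":
        W = float((0.5 - p.mean()) * math.sqrt(12.0 * K))
        return W, float(stats.norm.sf(W))
    if method == "inverse_chisq":
        L = float(np.sum(-2.0 * np.log(p)))
        return L, float(stats.chi2.sf(L, 2 * K))
    if method == "logit":
        S = float(np.sum(np.log(p / (1.0 - p))))
        return S, float(stats.t.cdf(S / _logit_scale(K), 5 * K + 4))
    raise ValidationError(f"unknown combination method {method!r}; choose from {COMBINE_METHODS}")


def _combiner_df(method: str, K: int) -> int | None:
    if method == "inverse_chisq":
        return 2 * K
    if method == "logit":
        return 5 * K + 4
    return None


def gsaq_test(
    gene_set: GeneSet,
    space: GeneSpace,
    qtls: QtlSet,
    plan: SamplingPlan,
    method: str = "inverse_normal",
    weights=None,
    tail: str = "inclusive",
) -> GsaqResult:
    """Run the full gene-sampling enrichment test.

    Draws K SRSWOR samples from G, computes per-sample hypergeometric
    upper-tail p-values against the genome-wide hit total, combines them by
    ``method``, and returns a result carrying everything needed to reproduce
    the run (seed, K, m, N, N_Q, method, tail, weights).
    """
    ps, xs = sample_pvalues(gene_set, space, qtls, plan, tail=tail)
    stat, comb = combine_pvalues(ps, method, weights=weights)
    counts = genome_hits(space, qtls)
    return GsaqResult(
        sample_nqhits=tuple(int(x) for x in xs),
        sample_pvalues=tuple(float(v) for v in ps),
        method=method,
        statistic=stat,
        df=_combiner_df(method, plan.K),
        combined_p=comb,
        K=plan.K,
        m=plan.m,
        seed=plan.seed,
        N=space.N,
        N_Q=int((counts > 0).sum()),
        n=gene_set.n,
        tail=tail,
        weights=None if weights is None else tuple(float(w) for w in np.asarray(weights)),
    )


def gsvq_test(
    gene_set: GeneSet, space: GeneSpace, qtls: QtlSet, tail: str = "inclusive"
) -> float:
    """Single-shot hypergeometric validation test on the whole gene set.

    p = P[X >= NQhits(G)] under Hypergeometric(N, N_Q, n) — no resampling.
    """
    counts = genome_hits(space, qtls)
    hit = counts > 0
    member_idx = np.array([space._index[g] for g in gene_set.member_ids])
    x = int(hit[member_idx].sum())
    return hypergeom_upper_p(x, space.N, int(hit.sum()), gene_set.n, tail=tail)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values across a family of tests."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
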