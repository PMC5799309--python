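"""Ranked gene lists and top-n gene sets from a two-class expression matrix.

Two stages mirror common microarray practice:

1. an optional preliminary filter keeping genes with |log2 fold change| >= 1
   and Welch two-sample t-test p < 0.05 (both thresholds adjustable);
2. a univariate / information-theoretic ranker producing a full ranked list,
   from which nested top-n gene sets are cut.

Rankers
-------
t_score   |mean1 - mean2| / sqrt(s1^2/n1 + s2^2/n2)   (Welch)
f_score   one-way ANOVA F across the two classes (pooled variance)
pcf       |Pearson correlation| with the 0/1 class vector
src       |Spearman rank correlation| with the 0/1 class vector
ig        information gain  I(X; C) of the discretized gene vs class
gr        gain ratio        I(X; C) / H(X)
su        symmetrical uncertainty  2 I(X; C) / (H(X) + H(C))
mrmr      greedy minimum-redundancy maximum-relevance, MID scheme:
          score at selection = I(X; C) - mean_j I(X; X_j) over already
          selected genes

Entropy-based scores use equal-frequency discretization into 3 bins and
log2 entropies.  Ties are broken lexicographically by gene id, so every
ranking is deterministic.  External rankers (e.g. wrappers around learners)
can be plugged in via :func:`register_ranker`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from ._errors import ValidationError
from .genome_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "RANKERS",
    "preliminary_filter",
    "rank_genes",
    "top_gene_set",
    "register_ranker",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by decreasing score (MRMR: greedy selection order)."""

    gene_ids: tuple[str, ...]
    scores: tuple[float, ...]
    method: str
    tie_break: str = "score-desc,gene_id-asc"

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValidationError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in ranked list")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _class_split(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    m0, m1 = expr.class_masks()
    if m0.sum() < 2 or m1.sum() < 2:
        raise ValidationError(
            f"each class needs >= 2 samples, got {int(m0.sum())} and {int(m1.sum())}"
        )
    return expr.values[:, m0], expr.values[:, m1]


def preliminary_filter(
    expr: ExpressionMatrix, fc_threshold: float = 1.0, p_threshold: float = 0.05
) -> ExpressionMatrix:
    """Keep genes with |log2 FC| >= fc_threshold AND Welch t-test p < p_threshold.

    On log2-scale expression the fold change is the difference of class means.
    Retained/removed counts are logged.
    """
    x0, x1 = _class_split(expr)
    fc = np.abs(x1.mean(axis=1) - x0.mean(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    keep = (fc >= fc_threshold) & (p < p_threshold)
    kept = [g for g, k in zip(expr.gene_ids, keep) if k]
    logger.info(
        "preliminary filter: retained %d / %d genes (|FC| >= %g, p < %g)",
        len(kept), len(expr.gene_ids), fc_threshold, p_threshold,
    )
    if not kept:
        raise ValidationError("preliminary filter removed every gene")
    return expr.subset_genes(kept)


# ---------------------------------------------------------------------------
# univariate scores


def _welch_t(expr: ExpressionMatrix) -> np.ndarray:
    x0, x1 = _class_split(expr)
    v0 = x0.var(axis=1, ddof=1) / x0.shape[1]
    v1 = x1.var(axis=1, ddof=1) / x1.shape[1]
    denom = np.sqrt(v0 + v1)
    diff = np.abs(x1.mean(axis=1) - x0.mean(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    return t


def _anova_f(expr: ExpressionMatrix) -> np.ndarray:
    x0, x1 = _class_split(expr)
    f, _ = stats.f_oneway(x0, x1, axis=1)
    return np.where(np.isnan(f), 0.0, f)


def _abs_corr(expr: ExpressionMatrix, rank_transform: bool) -> np.ndarray:
    m0, m1 = expr.class_masks()
    y = m1.astype(float)
    X = expr.values
    if rank_transform:
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    zero = sx == 0
    if zero.any():
        logger.warning("%d zero-variance gene(s) scored 0 by correlation", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(zero, 0.0, (Xc @ yc) / (sx * sy))
    return np.abs(r)


# ---------------------------------------------------------------------------
# information-theoretic scores on 3-bin equal-frequency discretization


def discretize_equal_frequency(values: np.ndarray, bins: int = 3) -> np.ndarray:
    """Per-row equal-frequency discretization into integer bin codes.

    Constant rows collapse into a single bin (and therefore carry zero
    entropy and zero mutual information).
    """
    X = np.asarray(values, dtype=float)
    qs = np.quantile(X, [i / bins for i in range(1, bins)], axis=1).T
    out = np.zeros(X.shape, dtype=np.int64)
    for j in range(bins - 1):
        out += (X > qs[:, [j]]).astype(np.int64)
    return out


def _entropy_from_counts(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _mi_discrete(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    """I(A; B) in bits from two integer code vectors."""
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    ha = _entropy_from_counts(joint.sum(axis=1))
    hb = _entropy_from_counts(joint.sum(axis=0))
    hab = _entropy_from_counts(joint.ravel())
    return max(0.0, ha + hb - hab)


def _info_scores(expr: ExpressionMatrix, kind: str, bins: int = 3) -> np.ndarray:
    codes = discretize_equal_frequency(expr.values, bins)
    _, cls = expr.class_masks()
    c = cls.astype(np.int64)
    hc = _entropy_from_counts(np.bincount(c, minlength=2))
    out = np.empty(len(expr.gene_ids))
    for i in range(codes.shape[0]):
        mi = _mi_discrete(codes[i], c, bins, 2)
        if kind == "ig":
            out[i] = mi
        else:
            hx = _entropy_from_counts(np.bincount(codes[i], minlength=bins))
            if kind == "gr":
                out[i] = mi / hx if hx > 0 else 0.0
            else:  # su
                out[i] = 2.0 * mi / (hx + hc) if hx + hc > 0 else 0.0
    return out


def _mrmr_order(
    expr: ExpressionMatrix, bins: int = 3
) -> tuple[list[int], list[float]]:
    """Greedy MID selection order over all genes.

    First pick maximizes relevance I(X; C); each subsequent pick maximizes
    I(X; C) - mean_j I(X; X_j) over genes already selected.
    """
    codes = discretize_equal_frequency(expr.values, bins)
    _, cls = expr.class_masks()
    c = cls.astype(np.int64)
    G = codes.shape[0]
    relevance = np.array([_mi_discrete(codes[i], c, bins, 2) for i in range(G)])
    ids = expr.gene_ids
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(G)
    remaining = set(range(G))
    while remaining:
        if not selected:
            crit = relevance.copy()
        else:
            crit = relevance - redundancy_sum / len(selected)
        best = min(remaining, key=lambda i: (-crit[i], ids[i]))
        selected.append(best)
        scores.append(float(crit[best]))
        remaining.discard(best)
        if remaining:
            rem = np.fromiter(remaining, dtype=int)
            for i in rem:
                redundancy_sum[i] += _mi_discrete(codes[i], codes[best], bins, bins)
    return selected, scores


_SCORE_FUNCS: dict[str, Callable[[ExpressionMatrix], np.ndarray]] = {
    "t_score": _welch_t,
    "f_score": _anova_f,
    "pcf": lambda e: _abs_corr(e, rank_transform=False),
    "src": lambda e: _abs_corr(e, rank_transform=True),
    "ig": lambda e: _info_scores(e, "ig"),
    "gr": lambda e: _info_scores(e, "gr"),
    "su": lambda e: _info_scores(e, "su"),
}

_EXTERNAL_RANKERS: dict[str, Callable[[ExpressionMatrix], RankedList]] = {}

RANKERS = ("t_score", "f_score", "pcf", "src", "ig", "gr", "su", "mrmr")


def register_ranker(name: str, fn: Callable[[ExpressionMatrix], RankedList]) -> None:
    """Plug in an external ranker (e.g. a learner wrapper) under ``name``.

    The callable receives the expression matrix and must return a
    :class:`RankedList` over exactly its gene ids.
    """
    if name in RANKERS:
        raise ValidationError(f"cannot shadow built-in ranker {name!r}")
    _EXTERNAL_RANKERS[name] = fn


def rank_genes(expr: ExpressionMatrix, method: str = "t_score") -> RankedList:
    """Score every gene by ``method`` and return the descending ranked list.

    Ties are broken lexicographically by gene id.  For ``mrmr`` the order is
    the greedy selection order and the recorded score is the MID criterion at
    the moment of selection (not monotone along the list by construction).
    """
    if method in _EXTERNAL_RANKERS:
        return _EXTERNAL_RANKERS[method](expr)
    if method == "mrmr":
        order, scores = _mrmr_order(expr)
        return RankedList(
            tuple(expr.gene_ids[i] for i in order),
            tuple(scores),
            method="mrmr",
            tie_break="greedy-order,gene_id-asc",
        )
    if method not in _SCORE_FUNCS:
        raise ValidationError(f"unknown ranker {method!r}; choose from {RANKERS}")
    scores = np.asarray(_SCORE_FUNCS[method](expr), dtype=float)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], expr.gene_ids[i]))
    return RankedList(
        tuple(expr.gene_ids[i] for i in order),
        tuple(float(scores[i]) for i in order),
        method=method,
    )


def top_gene_set(ranked: RankedList, size: int) -> GeneSet:
    """First ``size`` genes of the ranked list as a gene set.

    Nested by construction: top(s1) is a prefix of top(s2) for s1 <= s2.
    """
    if size < 1:
        raise ValidationError(f"gene set size must be >= 1, got {size}")
    if size > len(ranked):
        raise ValidationError(
            f"requested size {size} exceeds ranked list length {len(ranked)}"
        )
    return GeneSet(ranked.gene_ids[:size])
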