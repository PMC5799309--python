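"""Gene-set-size sweep: both enrichment tests over nested prefix gene sets.

For each ranker (or each supplied ranked list) and each requested size s,
the top-s prefix of the ranked list is evaluated: NQhits, the single-shot
hypergeometric p (GSVQ), and the resampling combined p (GSAQ) for every
requested combiner, with -log10 transforms alongside.  Benjamini-Hochberg
FDR is applied within each ranker's sweep separately — one family per
method — for every p-value column.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .enrichment import SamplingPlan, fdr_adjust, gsaq_test, gsvq_test
from .geneselect import RankedList, top_gene_set
from .genome_io import GeneSpace, QtlSet
from .overlap import hit_profile

__all__ = ["run_sweep"]


def _neglog10(p: np.ndarray) -> np.ndarray:
    return -np.log10(np.clip(np.asarray(p, dtype=float), 1e-300, None))


def run_sweep(
    ranked_lists: dict[str, RankedList],
    space: GeneSpace,
    qtls: QtlSet,
    sizes,
    K: int = 50,
    m: int | None = None,
    combiners=("inverse_normal",),
    seed: int = 0,
    tail: str = "inclusive",
) -> pd.DataFrame:
    """Evaluate nested prefix gene sets of every ranked list at each size.

    ``m=None`` uses the default sample size ceil(s/2) per prefix of size s;
    an explicit m must not exceed the smallest size.  Per-row sampling seeds
    are spawned deterministically from ``seed``.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValidationError("no gene set sizes given")
    if sorted(sizes) != sizes:
        raise ValidationError("sizes must be ascending")
    for name, ranked in ranked_lists.items():
        if sizes[-1] > len(ranked):
            raise ValidationError(
                f"size {sizes[-1]} exceeds ranked list {name!r} length {len(ranked)}"
            )
    if m is not None and m > sizes[0]:
        raise ValidationError(f"m={m} exceeds smallest gene set size {sizes[0]}")

    n_rows = len(ranked_lists) * len(sizes)
    seeds = np.random.SeedSequence(seed).generate_state(n_rows) % (2**31)
    rows = []
    i = 0
    for name, ranked in ranked_lists.items():
        for s in sizes:
            gs = top_gene_set(ranked, s)
            prof = hit_profile(gs, space, qtls)
            row = {
                "method": name,
                "size": s,
                "nqhits": prof.nqhits,
                "pr_gq": prof.pr_gq,
                "gsvq_p": gsvq_test(gs, space, qtls, tail=tail),
            }
            m_s = m if m is not None else math.ceil(s / 2)
            plan = SamplingPlan(K=K, m=m_s, seed=int(seeds[i]))
            for comb in combiners:
                res = gsaq_test(gs, space, qtls, plan, method=comb, tail=tail)
                row[f"gsaq_p_{comb}"] = res.combined_p
            row["K"], row["m"] = K, m_s
            rows.append(row)
            i += 1
    df = pd.DataFrame(rows)

    p_cols = ["gsvq_p"] + [f"gsaq_p_{c}" for c in combiners]
    for col in p_cols:
        df[f"{col}_neglog10"] = _neglog10(df[col].to_numpy())
    for col in p_cols:
        fdr = np.empty(len(df))
        for name in ranked_lists:
            mask = (df["method"] == name).to_numpy()
            fdr[mask] = fdr_adjust(df.loc[mask, col].to_numpy())
        df[f"{col}_fdr"] = fdr
    return df
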