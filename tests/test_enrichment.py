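import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from gsaq import (
    GeneSet,
    QtlSet,
    SamplingPlan,
    ValidationError,
    combine_pvalues,
    contingency_table,
    draw_gene_samples,
    fdr_adjust,
    gsaq_test,
    gsvq_test,
    hypergeom_upper_p,
    sample_pvalues,
)
from conftest import random_instance


def exact_upper_tail(x, N, N_Q, m):
    """Independent oracle: exact rational upper tail from integer binomials."""
    total = math.comb(N, m)
    count = sum(
        math.comb(N_Q, j) * math.comb(N - N_Q, m - j)
        for j in range(x, min(m, N_Q) + 1)
    )
    return Fraction(count, total)


def test_exact_oracle_agrees_with_literal_enumeration():
    """The combinatorial oracle itself is validated against a literal
    enumeration of every possible sample at tiny N."""
    for N, N_Q, m in [(6, 2, 3), (8, 4, 5), (10, 4, 5), (9, 9, 4)]:
        hit = [1] * N_Q + [0] * (N - N_Q)
        counts = {}
        for comb in itertools.combinations(range(N), m):
            x = sum(hit[i] for i in comb)
            counts[x] = counts.get(x, 0) + 1
        total = math.comb(N, m)
        for x in range(0, min(m, N_Q) + 1):
            tail = sum(v for k, v in counts.items() if k >= x)
            assert exact_upper_tail(x, N, N_Q, m) == Fraction(tail, total)


def test_worked_toy_tail_values():
    assert hypergeom_upper_p(3, 10, 4, 5) == pytest.approx(66 / 252, rel=1e-12)
    assert hypergeom_upper_p(0, 10, 4, 5) == 1.0
    assert hypergeom_upper_p(4, 10, 4, 5) == pytest.approx(6 / 252, rel=1e-12)


def test_tail_conventions():
    # exclusive tail reproduces the literal exceedance P[X > x]
    incl = hypergeom_upper_p(3, 10, 4, 5, tail="inclusive")
    excl = hypergeom_upper_p(3, 10, 4, 5, tail="exclusive")
    assert excl == pytest.approx(float(exact_upper_tail(4, 10, 4, 5)), rel=1e-12)
    assert excl < incl


def test_impossible_hit_count_rejected():
    with pytest.raises(ValidationError):
        hypergeom_upper_p(5, 10, 4, 5)
    with pytest.raises(ValidationError):
        hypergeom_upper_p(-1, 10, 4, 5)


def test_contingency_table_arithmetic(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    # sample of m=5 with 3 hits out of N=10, N_Q=4
    t = contingency_table(["g1", "g2", "g3", "g5", "g6"], space, qtls)
    assert (t.n_gkq, t.n_gkqc, t.n_gkc_q, t.n_gkc_qc) == (3, 2, 1, 4)
    assert (t.m, t.N_Q, t.N) == (5, 4, 10)
    # zero-hit sample
    t0 = contingency_table(["g5", "g6", "g7"], space, qtls)
    assert (t0.n_gkq, t0.n_gkqc) == (0, 3)
    # whole genome: complement row empty
    tN = contingency_table(list(space.gene_ids), space, qtls)
    assert (tN.n_gkc_q, tN.n_gkc_qc) == (0, 0)


def test_draw_gene_samples_contract(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    # m = n exhausts the population
    [only] = draw_gene_samples(gs, SamplingPlan(K=1, m=gs.n, seed=1))
    assert sorted(only) == sorted(gs.member_ids)
    # determinism and seed sensitivity
    a = draw_gene_samples(gs, SamplingPlan(K=4, m=3, seed=5))
    b = draw_gene_samples(gs, SamplingPlan(K=4, m=3, seed=5))
    c = draw_gene_samples(gs, SamplingPlan(K=4, m=3, seed=6))
    assert a == b
    assert a != c
    with pytest.raises(ValidationError):
        draw_gene_samples(gs, SamplingPlan(K=1, m=gs.n + 1, seed=0))
    with pytest.raises(ValidationError):
        SamplingPlan(K=0, m=1)


def test_inclusion_probability_is_m_over_n():
    """Monte-Carlo oracle: SRSWOR inclusion probability is m/n by symmetry."""
    space, qtls = random_instance(np.random.default_rng(3), n_genes=10, n_qtls=2)
    gs = GeneSet(list(space.gene_ids), space)
    samples = draw_gene_samples(gs, SamplingPlan(K=10_000, m=3, seed=42))
    freq = {g: 0 for g in gs.member_ids}
    for s in samples:
        for g in s:
            freq[g] += 1
    for g, c in freq.items():
        assert c / 10_000 == pytest.approx(0.3, abs=0.02)


def test_sample_pvalues_degenerate_cases(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    # empty QTL set: all x_k = 0, all p_k = 1
    ps, xs = sample_pvalues(gs, space, QtlSet([], trait="t"), SamplingPlan(K=5, m=3, seed=0))
    assert np.all(xs == 0) and np.all(ps == 1.0)
    # m = n: all K samples identical
    ps2, xs2 = sample_pvalues(gs, space, qtls, SamplingPlan(K=3, m=gs.n, seed=0))
    assert len(set(ps2)) == 1 and len(set(xs2)) == 1


# ---------------------------------------------------------------------------
# combiners


def test_inverse_normal_symmetry_and_derived_value():
    stat, p = combine_pvalues([0.5, 0.5], "inverse_normal")
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(0.5, abs=1e-12)

    w = [1 / math.sqrt(2)] * 2
    stat, p = combine_pvalues([0.05, 0.05], "inverse_normal", weights=w)
    # T = sqrt(2) * Phi^-1(0.05)
    assert stat == pytest.approx(math.sqrt(2) * stats.norm.ppf(0.05), rel=1e-10)
    assert stat == pytest.approx(-2.3262, abs=5e-5)
    assert p == pytest.approx(0.0100, abs=5e-5)


def test_mean_p_derived_value():
    stat, p = combine_pvalues([0.1, 0.2, 0.3], "mean_p")
    assert stat == pytest.approx(0.3 * math.sqrt(36), rel=1e-12)  # W = 1.8
    assert p == pytest.approx(float(stats.norm.sf(1.8)), rel=1e-10)
    assert p == pytest.approx(0.0359, abs=5e-5)


def test_inverse_chisq_closed_form():
    L = -2 * (math.log(0.1) + math.log(0.2))
    stat, p = combine_pvalues([0.1, 0.2], "inverse_chisq")
    assert stat == pytest.approx(L, rel=1e-12)
    # chi2 with 4 df: survival = e^{-L/2} (1 + L/2)
    assert p == pytest.approx(math.exp(-L / 2) * (1 + L / 2), rel=1e-10)


def test_logit_symmetry():
    stat, p = combine_pvalues([0.5] * 4, "logit")
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(0.5, abs=1e-12)


def test_combiner_input_validation():
    with pytest.raises(ValidationError):
        combine_pvalues([], "inverse_normal")
    with pytest.raises(ValidationError):
        combine_pvalues([0.5, 1.5], "inverse_normal")
    with pytest.raises(ValidationError):
        combine_pvalues([0.5, 0.5], "inverse_normal", weights=[1.0, 1.0])  # ||w|| != 1
    with pytest.raises(ValidationError):
        combine_pvalues([0.5], "nope")
    # extreme p-values must not produce infinities
    for method in ("inverse_normal", "mean_p", "inverse_chisq", "logit"):
        stat, p = combine_pvalues([0.0, 1.0], method)
        assert math.isfinite(stat) and 0.0 <= p <= 1.0


@pytest.mark.parametrize("method", ["inverse_normal", "mean_p", "inverse_chisq", "logit"])
def test_combiners_are_monotone(method):
    """Decreasing any single p_k never increases the combined p."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        p = rng.uniform(0.01, 0.99, size=6)
        _, base = combine_pvalues(p, method)
        k = rng.integers(0, 6)
        q = p.copy()
        q[k] *= rng.uniform(0.1, 0.9)
        _, lower = combine_pvalues(q, method)
        assert lower <= base + 1e-12


@pytest.mark.parametrize("method", ["inverse_normal", "mean_p", "inverse_chisq", "logit"])
def test_combined_p_uniform_under_independent_uniform_inputs(method):
    """With truly independent U[0,1] p_k injected directly, every combiner's
    combined p is Uniform[0,1] (KS at alpha=0.01, 10,000 replicates)."""
    rng = np.random.default_rng(99)
    K = 8
    ps = rng.uniform(size=(10_000, K))
    combined = np.array([combine_pvalues(row, method)[1] for row in ps])
    d, pval = stats.kstest(combined, "uniform")
    assert pval > 0.01


# ---------------------------------------------------------------------------
# full tests


def test_gsvq_toy(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    assert gsvq_test(gs, space, qtls) == pytest.approx(66 / 252, rel=1e-12)


def test_gsvq_degenerate(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    assert gsvq_test(gs, space, QtlSet([], trait="t")) == 1.0  # NQhits = 0
    assert gsvq_test(GeneSet(list(space.gene_ids), space), space, qtls) == 1.0


def test_gsaq_reduces_to_gsvq_at_k1_m_n(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    res = gsaq_test(gs, space, qtls, SamplingPlan(K=1, m=gs.n, seed=0),
                    method="inverse_normal", weights=[1.0])
    assert res.combined_p == pytest.approx(gsvq_test(gs, space, qtls), rel=1e-12)


def test_gsaq_result_determinism(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    plan = SamplingPlan(K=6, m=4, seed=123)
    a = gsaq_test(gs, space, qtls, plan, method="logit")
    b = gsaq_test(gs, space, qtls, plan, method="logit")
    assert a == b  # bit-identical dataclasses
    assert a.to_dict() == b.to_dict()


def test_gsaq_records_reproduction_metadata(ten_gene_instance):
    space, qtls, gs = ten_gene_instance
    res = gsaq_test(gs, space, qtls, SamplingPlan(K=4, m=3, seed=9), method="inverse_chisq")
    assert (res.K, res.m, res.seed) == (4, 3, 9)
    assert (res.N, res.N_Q, res.n) == (10, 4, 5)
    assert res.df == 8  # chi2 with 2K df
    assert len(res.sample_pvalues) == 4


def test_fdr_adjust_hand_computation():
    np.testing.assert_allclose(
        fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], rtol=1e-12
    )
    assert fdr_adjust([1.0]) == pytest.approx([1.0])
    rng = np.random.default_rng(5)
    p = rng.uniform(size=20)
    q = fdr_adjust(p)
    assert np.all(q >= p) and np.all(q <= 1.0)
    with pytest.raises(ValidationError):
        fdr_adjust([0.5, 1.2])
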