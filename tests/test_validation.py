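"""Validation battery: differential expression, stratified coexpression and
leave-one-out single-gene AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from eqtligate.data_model import DataError, log2p1
from eqtligate.validation import (
    CONTRAST_DISEASE,
    CONTRAST_VARIANT_NORMAL,
    coexpression,
    de_battery,
    differential_expression,
    loo_auc,
    two_group_t,
)

# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def test_null_groups_give_null_statistic():
    rng = np.random.default_rng(0)
    v = rng.normal(5, 1, size=200)
    _, t, p = two_group_t(v[:100], v[100:])
    assert abs(t) < 2.5
    assert p > 0.01


def test_t_matches_brute_force_and_library():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 20)
    effect, t, p = two_group_t(a, b)
    # brute-force pooled-variance formula
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 33
    t_ref = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / 15 + 1 / 20))
    assert t == pytest.approx(t_ref, abs=1e-10)
    ref = stats.ttest_ind(b, a, equal_var=True)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_antisymmetric_in_group_order():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
    e1, t1, p1 = two_group_t(a, b)
    e2, t2, p2 = two_group_t(b, a)
    assert t1 == pytest.approx(-t2)
    assert e1 == pytest.approx(-e2)
    assert p1 == pytest.approx(p2)


def test_planted_disease_gene_strongly_differential(power_cohort):
    c = power_cohort
    gene = sorted(c.truth.planted_gene_ids)[0]
    res = differential_expression(gene, c.expression.row(gene),
                                  c.samples.disease_mask, CONTRAST_DISEASE)
    assert res.testable and res.p < 0.001


def test_absent_variant_group_is_untestable():
    """No variant carriers among normals: the normal-stratum contrast is
    reported untestable instead of erroring."""
    rng = np.random.default_rng(3)
    n = 40
    disease = np.array([True] * 20 + [False] * 20)
    codes = np.where(disease, rng.integers(0, 3, n), 0).astype(np.int8)
    values = rng.uniform(1, 5, n)
    results = {r.contrast: r for r in de_battery("g", values, codes, disease)}
    assert not results[CONTRAST_VARIANT_NORMAL].testable


# ---------------------------------------------------------------------------
# coexpression
# ---------------------------------------------------------------------------


def test_exact_linear_pair_perfect_correlation():
    a = np.arange(1.0, 13.0)
    b = 2 * a + 1
    variant = np.zeros(12, dtype=bool)
    variant[:6] = True
    for r in coexpression("a", a, "b", b, variant):
        assert r.r == pytest.approx(1.0)


def test_spearman_is_pearson_on_ranks():
    rng = np.random.default_rng(4)
    a, b = rng.uniform(0, 9, 30), rng.uniform(0, 9, 30)
    res = {(r.method, r.stratum): r
           for r in coexpression("a", a, "b", b, np.zeros(30, dtype=bool))}
    ra = stats.rankdata(log2p1(a))
    rb = stats.rankdata(log2p1(b))
    assert res[("spearman", "nonvariant")].r == pytest.approx(
        stats.pearsonr(ra, rb).statistic, abs=1e-12)


def test_monotone_transform_invariance_of_rank_methods():
    rng = np.random.default_rng(5)
    a, b = rng.uniform(0, 5, 25), rng.uniform(0, 5, 25)
    base = {r.method: r.r for r in
            coexpression("a", a, "b", b, np.zeros(25, dtype=bool))
            if r.stratum == "nonvariant"}
    warped = {r.method: r.r for r in
              coexpression("a", np.expm1(a), "b", b, np.zeros(25, dtype=bool))
              if r.stratum == "nonvariant"}
    for method in ("spearman", "kendall"):
        assert base[method] == pytest.approx(warped[method], abs=1e-12)


def test_constant_stratum_flagged_undefined():
    a = np.ones(20)
    b = np.arange(20.0)
    res = coexpression("a", a, "b", b, np.zeros(20, dtype=bool))
    assert all(not r.defined for r in res if r.stratum == "nonvariant")


def test_correlation_only_in_nonvariant_stratum():
    """A shared factor present only in nonvariant samples: significant
    correlation there, none among variant samples (all three methods)."""
    rng = np.random.default_rng(6)
    n = 60
    factor = rng.normal(0, 2, n)
    nonvar_a = 5 + factor + rng.normal(0, 0.3, n)
    nonvar_b = 5 + factor + rng.normal(0, 0.3, n)
    var_a = 5 + rng.normal(0, 2, n)
    var_b = 5 + rng.normal(0, 2, n)
    a = np.clip(np.concatenate([var_a, nonvar_a]), 0, None)
    b = np.clip(np.concatenate([var_b, nonvar_b]), 0, None)
    variant = np.array([True] * n + [False] * n)
    for r in coexpression("a", a, "b", b, variant):
        if r.stratum == "nonvariant":
            assert r.p < 0.05
        else:
            assert r.p > 0.05


# ---------------------------------------------------------------------------
# LOO AUC
# ---------------------------------------------------------------------------


def test_perfectly_separated_feature():
    x = np.concatenate([np.zeros(10), np.ones(10) + 1])
    y = np.array([False] * 10 + [True] * 10)
    assert loo_auc(x, y).auc == 1.0


def test_null_feature_auc_near_half():
    rng = np.random.default_rng(7)
    x = rng.normal(size=400)
    y = rng.random(400) < 0.5
    assert abs(loo_auc(x, y).auc - 0.5) < 0.05


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, derandomize=True)
def test_auc_orientation_symmetry(seed):
    """AUC(feature) + AUC(-feature) = 1 for tie-free data."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=30) + np.linspace(0, 1, 30)
    y = np.array([False] * 15 + [True] * 15)
    assert loo_auc(x, y).auc + loo_auc(-x, y).auc == pytest.approx(1.0)


def test_loo_decisions_rank_like_raw_feature():
    """Held-out midpoint decisions are monotone in the feature per fold, so
    the LOO AUC tracks the plain Mann-Whitney AUC of the raw feature."""
    rng = np.random.default_rng(8)
    y = rng.random(100) < 0.5
    x = rng.normal(size=100) + 0.8 * y
    direct = roc_auc_score(y, x)
    assert loo_auc(x, y).auc == pytest.approx(direct, abs=0.01)


def test_single_class_rejected():
    with pytest.raises(DataError):
        loo_auc(np.arange(6.0), np.ones(6, dtype=bool))
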