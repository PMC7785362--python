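"""Dual eQTL algorithms: ANOVA decomposition, covariate-adjusted OLS,
BH-FDR and the candidate intersection."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from eqtligate.data_model import SnpGeneMap
from eqtligate.eqtl import (
    STRAT_CARRIERS,
    STRAT_DISEASE,
    Untestable,
    anova_pass_set,
    bh_adjust,
    fit_additive_model,
    intersect_algorithms,
    linreg_pass_set,
    oneway_anova,
    run_anova_eqtl,
    run_linreg_eqtl,
)
from eqtligate.synthetic_data import SimulationConfig, simulate_cohort

# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------


def test_anova_hand_computed_example():
    s_a, s_e, f, p, s, n = oneway_anova([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
    assert s_a == pytest.approx(13.5)
    assert s_e == pytest.approx(4.0)
    assert f == pytest.approx(13.5)  # (13.5/1) / (4/4)
    assert (s, n) == (2, 6)


def test_anova_no_variation():
    s_a, s_e, f, p, _, _ = oneway_anova([2.0] * 6, [0, 0, 1, 1, 2, 2])
    assert s_a == 0.0 and f == 0.0 and p == 1.0


def test_anova_variance_decomposition_and_library_oracle():
    rng = np.random.default_rng(3)
    values = rng.normal(size=60)
    groups = rng.integers(0, 3, size=60)
    s_a, s_e, f, p, s, n = oneway_anova(values, groups)
    total_ss = ((values - values.mean()) ** 2).sum()
    assert s_a + s_e == pytest.approx(total_ss, abs=1e-10)
    ref = stats.f_oneway(*(values[groups == g] for g in range(3)))
    assert f == pytest.approx(ref.statistic, rel=1e-10)
    assert p == pytest.approx(ref.pvalue, rel=1e-8)


def test_anova_f_equals_squared_t_for_two_groups():
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=20), rng.normal(0.5, 1, size=25)
    values = np.concatenate([a, b])
    groups = np.array([0] * 20 + [1] * 25)
    _, _, f, p, _, _ = oneway_anova(values, groups)
    t = stats.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t.statistic ** 2, rel=1e-8)
    assert p == pytest.approx(t.pvalue, rel=1e-8)


def test_anova_undersized_groups_dropped_then_untestable():
    # the singleton group is dropped, leaving one usable group
    with pytest.raises(Untestable):
        oneway_anova([1.0, 2.0, 3.0, 9.0], [0, 0, 0, 1])


# ---------------------------------------------------------------------------
# additive linear model
# ---------------------------------------------------------------------------


def test_linfit_constant_expression_is_degenerate():
    fit = fit_additive_model(np.ones(10), np.arange(10) % 3, np.zeros(10))
    assert fit.beta == 0.0 and fit.p == 1.0 and fit.flag == "degenerate"


def test_linfit_exact_linear_perfect_fit():
    x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
    g = 2 + 1.5 * x
    fit = fit_additive_model(g, x, np.zeros(6))
    assert fit.beta == pytest.approx(1.5)
    assert fit.flag == "perfect_fit" and fit.se_beta == 0.0


def test_linfit_matches_statsmodels_ols():
    rng = np.random.default_rng(8)
    n = 50
    x = rng.integers(0, 3, size=n).astype(float)
    k = (rng.random(n) < 0.5).astype(float)
    g = 1.0 + 0.8 * k + 0.5 * x + rng.normal(0, 0.3, n)
    fit = fit_additive_model(g, x, k)
    ref = sm.OLS(g, sm.add_constant(np.column_stack([k, x]))).fit()
    assert fit.alpha == pytest.approx(ref.params[0], abs=1e-8)
    assert fit.gamma == pytest.approx(ref.params[1], abs=1e-8)
    assert fit.beta == pytest.approx(ref.params[2], abs=1e-8)
    assert fit.se_beta == pytest.approx(ref.bse[2], abs=1e-8)
    assert fit.t == pytest.approx(ref.tvalues[2], abs=1e-6)
    assert fit.p == pytest.approx(ref.pvalues[2], abs=1e-8)


def test_linfit_untestable_designs():
    k = np.array([0, 0, 1, 1, 0, 1], dtype=float)
    with pytest.raises(Untestable, match="constant genotype"):
        fit_additive_model(np.ones(6), np.ones(6), k)
    with pytest.raises(Untestable, match="collinear"):
        fit_additive_model(np.arange(6, dtype=float), k, k)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("pvals, expected", [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.005, 0.2, 0.9], [0.015, 0.3, 0.9]),
    ([0.37], [0.37]),
])
def test_bh_step_up_definition(pvals, expected):
    np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# eQTL runners
# ---------------------------------------------------------------------------


def test_planted_eqtl_passes_both_algorithms(power_cohort):
    c = power_cohort
    anova = run_anova_eqtl(c.genotypes, c.expression, c.samples, c.snp_gene_map)
    linreg = run_linreg_eqtl(c.genotypes, c.expression, c.samples, c.snp_gene_map)
    a_pass, l_pass = anova_pass_set(anova), linreg_pass_set(linreg)
    assert c.truth.planted_snp_ids <= a_pass
    assert c.truth.planted_snp_ids <= l_pass
    # planted SNPs reach significance in the disease genotype-group stratification
    for r in anova:
        if r.snp_id in c.truth.planted_snp_ids and r.stratification == STRAT_DISEASE:
            assert r.q < 0.05


def test_anova_null_pass_rate_is_small(null_cohort):
    c = null_cohort
    anova = run_anova_eqtl(c.genotypes, c.expression, c.samples, c.snp_gene_map)
    tested = {r.snp_id for r in anova}
    assert len(anova_pass_set(anova)) <= 0.01 * len(tested)


def test_zero_variant_carriers_in_normals_skips_stratification_a():
    """A SNP whose variants are absent from normal samples is untestable in
    the carrier stratification but still testable in disease samples."""
    cfg = SimulationConfig(n_disease=80, n_normal=40, n_snps=2, n_genes=40,
                           n_planted=2, planted_control_alt_freq=1e-6, seed=13)
    c = simulate_cohort(cfg)
    snp = sorted(c.truth.planted_snp_ids)[0]
    assert (c.genotypes.row(snp)[~c.samples.disease_mask] >= 1).sum() == 0
    anova = run_anova_eqtl(c.genotypes, c.expression, c.samples, c.snp_gene_map)
    strats = {r.stratification for r in anova if r.snp_id == snp}
    assert STRAT_CARRIERS not in strats
    assert STRAT_DISEASE in strats


def test_covariate_absorbs_disease_shift():
    """Genes shifted by disease only (beta=0) must not pass the adjusted
    model, and omitting the covariate inflates false positives."""
    cfg = SimulationConfig(n_disease=300, n_normal=300, n_snps=60, n_genes=120,
                           n_planted=30, eqtl_beta=0.0, disease_shift=3.0, seed=17)
    c = simulate_cohort(cfg)
    with_k = linreg_pass_set(run_linreg_eqtl(
        c.genotypes, c.expression, c.samples, c.snp_gene_map))
    without_k = linreg_pass_set(run_linreg_eqtl(
        c.genotypes, c.expression, c.samples, c.snp_gene_map,
        include_covariate=False))
    planted = c.truth.planted_snp_ids
    assert not (with_k & planted)
    assert len(without_k & planted) > len(with_k & planted)


def test_linreg_null_cohort_no_passes(null_cohort):
    c = null_cohort
    linreg = run_linreg_eqtl(c.genotypes, c.expression, c.samples, c.snp_gene_map)
    assert linreg_pass_set(linreg) == set()


def test_intersection_rule():
    snp_map = SnpGeneMap({"a": "gA", "b": "gB", "c": "gB", "d": "gD"})
    cs = intersect_algorithms({"a", "b", "c"}, {"b", "c", "d"}, snp_map)
    assert cs.candidate_snps == {"b", "c"}
    assert cs.candidate_genes == {"gB"}
    assert cs.provenance["a"] == ("anova",)
    assert cs.provenance["b"] == ("anova", "linreg")
    empty = intersect_algorithms({"a"}, {"d"}, snp_map)
    assert empty.candidate_snps == set() and empty.candidate_genes == set()
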