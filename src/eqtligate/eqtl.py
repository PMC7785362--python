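"""Dual cis-eQTL analysis and the candidate intersection.

Two algorithms are run over every candidate SNP and its cis-mapped gene:

1. One-way ANOVA over genotype-defined groups under two sample
   stratifications —
   (A) among variant carriers (genotype >= 1), disease vs normal samples;
   (B) among disease samples, the genotype groups present (s up to 3).
   The F statistic is F = (S_A/(s-1)) / (S_E/(n-s)) with S_A/S_E the
   between-/within-group sums of squares. BH-FDR is applied within each
   stratification and a SNP passes the ANOVA algorithm if q < fdr in either
   (the two stratifications are merged by union).
2. A covariate-adjusted additive linear model g = alpha + gamma*k + beta*x
   + eps, with x the additive genotype code and k the disease indicator;
   beta is tested with a Student t (n-3 residual df) and BH-FDR across all
   cis pairs.

SNPs passing BOTH algorithms are the candidate risk SNPs; their mapped
genes are the candidate genes. Expression enters both models as
log2(FPKM + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    MISSING,
    DataError,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleTable,
    SnpGeneMap,
    log2p1,
)

logger = logging.getLogger("eqtligate")

STRAT_CARRIERS = "variant_carriers_disease_vs_normal"
STRAT_DISEASE = "disease_genotype_groups"
STRAT_ALL_GENOTYPE = "all_samples_genotype_groups"  # alternative reading of (A)


class Untestable(Exception):
    """A SNP-gene pair that cannot be tested (with a reason)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvals = np.asarray(pvals, dtype=np.float64)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# algorithm 1: one-way ANOVA over mutation groups
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    snp_id: str
    gene_id: str
    stratification: str
    s: int              # number of groups
    n: int              # samples used
    s_a: float          # between-group sum of squares
    s_e: float          # within-group sum of squares
    f: float
    p: float
    q: float = float("nan")
    degenerate: bool = False


def oneway_anova(values, groups, min_group_size: int = 2
                 ) -> tuple[float, float, float, float, int, int]:
    """Classical one-way ANOVA decomposition.

    Groups with fewer than ``min_group_size`` members are dropped (and s
    reduced). Returns (S_A, S_E, F, p, s, n); raises :class:`Untestable`
    when fewer than two usable groups remain.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise DataError("oneway_anova: values and groups differ in length")
    chunks = []
    for g in pd.unique(groups):
        v = values[groups == g]
        if v.size >= min_group_size:
            chunks.append(v)
    s = len(chunks)
    if s < 2:
        raise Untestable("fewer than 2 usable groups")
    n = sum(v.size for v in chunks)
    if n <= s:
        raise Untestable("no within-group degrees of freedom")
    grand = np.concatenate(chunks).mean()
    s_a = sum(v.size * (v.mean() - grand) ** 2 for v in chunks)
    s_e = sum(((v - v.mean()) ** 2).sum() for v in chunks)
    if s_e <= 0.0:
        if s_a <= 0.0:
            return 0.0, 0.0, 0.0, 1.0, s, n  # no variation at all
        return float(s_a), 0.0, float("inf"), 0.0, s, n  # degenerate: perfect separation
    f = (s_a / (s - 1)) / (s_e / (n - s))
    p = float(stats.f.sf(f, s - 1, n - s))
    return float(s_a), float(s_e), float(f), p, s, n


def run_anova_eqtl(gm: GenotypeMatrix,
                   expr: ExpressionMatrix,
                   samples: SampleTable,
                   snp_map: SnpGeneMap,
                   fdr: float = 0.05,
                   candidate_ids: set[str] | None = None,
                   stratification_a: str = STRAT_CARRIERS) -> list[AnovaResult]:
    """ANOVA eQTL under both stratifications with per-stratification BH-FDR.

    ``stratification_a`` selects the reading of the first stratification:
    :data:`STRAT_CARRIERS` (default; variant carriers, disease vs normal) or
    :data:`STRAT_ALL_GENOTYPE` (genotype groups in all samples).
    """
    if stratification_a not in (STRAT_CARRIERS, STRAT_ALL_GENOTYPE):
        raise DataError(f"unknown stratification {stratification_a!r}")
    disease = samples.disease_mask
    pheno = np.asarray(samples.phenotypes)
    results: list[AnovaResult] = []
    for rec, row in zip(gm.snps, gm.codes):
        if candidate_ids is not None and rec.snp_id not in candidate_ids:
            continue
        gene = snp_map.gene_of(rec.snp_id)
        if gene is None or gene not in expr:
            continue
        called = row != MISSING
        y = log2p1(expr.row(gene))
        for strat in (stratification_a, STRAT_DISEASE):
            if strat == STRAT_CARRIERS:
                mask = called & (row >= 1)
                labels = pheno[mask]
            elif strat == STRAT_ALL_GENOTYPE:
                mask = called
                labels = row[mask]
            else:  # disease samples, genotype groups
                mask = called & disease
                labels = row[mask]
            try:
                s_a, s_e, f, p, s, n = oneway_anova(y[mask], labels)
            except Untestable as exc:
                logger.debug("ANOVA %s/%s [%s] untestable: %s",
                             rec.snp_id, gene, strat, exc.reason)
                continue
            results.append(AnovaResult(rec.snp_id, gene, strat, s, n,
                                       s_a, s_e, f, p,
                                       degenerate=(s_e == 0.0)))
    for strat in {r.stratification for r in results}:
        idx = [i for i, r in enumerate(results) if r.stratification == strat]
        qs = bh_adjust([results[i].p for i in idx])
        for i, q in zip(idx, qs):
            results[i].q = float(q)
    return results


def anova_pass_set(results: list[AnovaResult], fdr: float = 0.05) -> set[str]:
    """SNPs with q < fdr in either stratification (merged by union)."""
    return {r.snp_id for r in results if r.q < fdr}


# ---------------------------------------------------------------------------
# algorithm 2: covariate-adjusted additive linear model
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    snp_id: str = ""
    gene_id: str = ""
    alpha: float = float("nan")   # intercept
    gamma: float = float("nan")   # disease-covariate weight
    beta: float = float("nan")    # per-ALT-allele expression slope
    se_beta: float = float("nan")
    t: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    n: int = 0
    flag: str = ""                # "", "degenerate", "perfect_fit"


def fit_additive_model(g, x, k, include_covariate: bool = True) -> LinearFit:
    """OLS of expression ``g`` on [1, k, x]; Student t test of the x slope.

    Raises :class:`Untestable` when x is constant or the design is rank
    deficient ("collinear"). A zero-residual fit is flagged rather than
    rejected: p = 1 when the slope is also ~0 ("degenerate"), p = 0
    otherwise ("perfect_fit").
    """
    g = np.asarray(g, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    n = g.size
    if x.size != n or k.size != n:
        raise DataError("fit_additive_model: vector lengths differ")
    if np.ptp(x) == 0.0:
        raise Untestable("constant genotype")
    if include_covariate and np.ptp(k) == 0.0:
        include_covariate = False  # constant covariate carries no information
    cols = [np.ones(n), k, x] if include_covariate else [np.ones(n), x]
    X = np.column_stack(cols)
    p_params = X.shape[1]
    if n < p_params + 1:
        raise Untestable("too few samples for residual degrees of freedom")
    if np.linalg.matrix_rank(X) < p_params:
        raise Untestable("collinear")
    coef, _, _, _ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - X @ coef
    rss = float(resid @ resid)
    df = n - p_params
    beta = float(coef[-1])
    alpha = float(coef[0])
    gamma = float(coef[1]) if include_covariate else 0.0
    scale = max(float(g @ g), 1.0)
    if rss <= 1e-12 * scale:
        if abs(beta) <= 1e-10:
            return LinearFit(alpha=alpha, gamma=gamma, beta=0.0, se_beta=0.0,
                             t=0.0, p=1.0, n=n, flag="degenerate")
        return LinearFit(alpha=alpha, gamma=gamma, beta=beta, se_beta=0.0,
                         t=float("inf"), p=0.0, n=n, flag="perfect_fit")
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se_beta = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    t = beta / se_beta
    p = float(2.0 * stats.t.sf(abs(t), df))
    return LinearFit(alpha=alpha, gamma=gamma, beta=beta, se_beta=se_beta,
                     t=float(t), p=p, n=n)


def run_linreg_eqtl(gm: GenotypeMatrix,
                    expr: ExpressionMatrix,
                    samples: SampleTable,
                    snp_map: SnpGeneMap,
                    fdr: float = 1e-6,
                    candidate_ids: set[str] | None = None,
                    include_covariate: bool = True) -> list[LinearFit]:
    """Additive-model eQTL over all cis pairs with BH-FDR across pairs."""
    disease = samples.disease_mask.astype(np.float64)
    fits: list[LinearFit] = []
    for rec, row in zip(gm.snps, gm.codes):
        if candidate_ids is not None and rec.snp_id not in candidate_ids:
            continue
        gene = snp_map.gene_of(rec.snp_id)
        if gene is None or gene not in expr:
            continue
        called = row != MISSING
        y = log2p1(expr.row(gene))[called]
        try:
            fit = fit_additive_model(y, row[called].astype(np.float64),
                                     disease[called],
                                     include_covariate=include_covariate)
        except Untestable as exc:
            logger.debug("linreg %s/%s untestable: %s", rec.snp_id, gene, exc.reason)
            continue
        fits.append(replace(fit, snp_id=rec.snp_id, gene_id=gene))
    qs = bh_adjust([f.p for f in fits])
    for fit, q in zip(fits, qs):
        fit.q = float(q)
    return fits


def linreg_pass_set(fits: list[LinearFit], fdr: float = 1e-6) -> set[str]:
    return {f.snp_id for f in fits if f.q < fdr}


# ---------------------------------------------------------------------------
# intersection of the two algorithms
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Candidate risk SNPs (passed both algorithms) and their mapped genes."""

    candidate_snps: set[str]
    candidate_genes: set[str]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)


def intersect_algorithms(anova_pass: set[str],
                         linreg_pass: set[str],
                         snp_map: SnpGeneMap) -> CandidateSet:
    """SNPs identified by both algorithms become candidate risk SNPs."""
    snps = set(anova_pass) & set(linreg_pass)
    if not snps:
        logger.warning("eQTL intersection is empty: no candidate risk SNPs")
    genes = {snp_map.gene_of(s) for s in snps} - {None}
    provenance = {}
    for s in set(anova_pass) | set(linreg_pass):
        algos = tuple(name for name, members in
                      (("anova", anova_pass), ("linreg", linreg_pass))
                      if s in members)
        provenance[s] = algos
    return CandidateSet(snps, genes, provenance)


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.snp_id, r.gene_id, r.stratification, r.s, r.n, r.s_a, r.s_e,
          r.f, r.p, r.q, r.degenerate) for r in results],
        columns=["snp_id", "gene_id", "stratification", "s", "n", "s_a",
                 "s_e", "f", "p", "q", "degenerate"])


def linreg_table(fits: list[LinearFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.snp_id, f.gene_id, f.n, f.alpha, f.gamma, f.beta, f.se_beta,
          f.t, f.p, f.q, f.flag) for f in fits],
        columns=["snp_id", "gene_id", "n", "alpha", "gamma", "beta",
                 "se_beta", "t", "p", "q", "flag"])
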