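"""Post-hoc validation battery for nominated susceptibility genes.

Three independent lines of evidence per gene:

* four differential-expression contrasts (disease vs normal; variant vs
  nonvariant carriers of the gene's risk SNP in all / normal-only /
  disease-only samples), via a pooled-variance two-sample t-test on
  log2(FPKM + 1);
* coexpression with an interacting known causal gene, computed with the
  Pearson, Spearman and Kendall methods separately in variant and
  nonvariant samples (an eQTL that disrupts co-regulation shows
  significance only in the nonvariant stratum);
* single-gene classification: leave-one-out cross-validated AUC of a
  one-feature linear decision rule (class-mean midpoint; any linear-kernel
  margin rule on one feature is monotone in that feature, so ranks — hence
  AUC — are rule-invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data_model import MISSING, DataError, log2p1

logger = logging.getLogger("eqtligate")

CONTRAST_DISEASE = "disease_vs_normal"
CONTRAST_VARIANT_ALL = "variant_vs_nonvariant_all"
CONTRAST_VARIANT_NORMAL = "variant_vs_nonvariant_normal"
CONTRAST_VARIANT_DISEASE = "variant_vs_nonvariant_disease"

COEXPR_METHODS = ("pearson", "spearman", "kendall")


@dataclass
class DeResult:
    gene_id: str
    contrast: str
    effect: float   # difference of log2 group means (group1 - group0)
    t: float
    p: float
    testable: bool
    n0: int = 0
    n1: int = 0


def two_group_t(values0, values1) -> tuple[float, float, float]:
    """Pooled-variance two-sample t on already-transformed values.

    Returns (effect, t, p) where effect = mean(values1) - mean(values0).
    Equivalent to the slope test of a two-group linear model.
    """
    v0 = np.asarray(values0, dtype=np.float64)
    v1 = np.asarray(values1, dtype=np.float64)
    n0, n1 = v0.size, v1.size
    if n0 < 2 or n1 < 2:
        raise DataError("two_group_t: each group needs >=2 samples")
    effect = v1.mean() - v0.mean()
    df = n0 + n1 - 2
    sp2 = (((v0 - v0.mean()) ** 2).sum() + ((v1 - v1.mean()) ** 2).sum()) / df
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    if se == 0.0:
        t = 0.0 if effect == 0.0 else np.sign(effect) * np.inf
        p = 1.0 if effect == 0.0 else 0.0
    else:
        t = effect / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return float(effect), float(t), float(p)


def differential_expression(gene_id: str,
                            values: np.ndarray,
                            group_mask: np.ndarray,
                            contrast: str) -> DeResult:
    """One contrast for one gene; ``group_mask`` selects group 1.

    Untestable (a group with <2 samples — e.g. variants absent from normal
    samples) yields ``testable=False`` rather than an error.
    """
    y = log2p1(values)
    mask = np.asarray(group_mask, dtype=bool)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n0 < 2 or n1 < 2:
        return DeResult(gene_id, contrast, float("nan"), float("nan"),
                        float("nan"), False, n0, n1)
    effect, t, p = two_group_t(y[~mask], y[mask])
    return DeResult(gene_id, contrast, effect, t, p, True, n0, n1)


def de_battery(gene_id: str,
               expression: np.ndarray,
               snp_codes: np.ndarray,
               disease_mask: np.ndarray) -> list[DeResult]:
    """The four contrasts for one gene and its risk SNP."""
    disease_mask = np.asarray(disease_mask, dtype=bool)
    called = snp_codes != MISSING
    variant = called & (snp_codes >= 1)
    out = [differential_expression(gene_id, expression, disease_mask,
                                   CONTRAST_DISEASE)]
    for contrast, scope in ((CONTRAST_VARIANT_ALL, np.ones_like(disease_mask)),
                            (CONTRAST_VARIANT_NORMAL, ~disease_mask),
                            (CONTRAST_VARIANT_DISEASE, disease_mask)):
        sel = scope.astype(bool) & called
        out.append(differential_expression(
            gene_id, expression[sel], variant[sel], contrast))
    return out


@dataclass
class CorrelationResult:
    gene_a: str
    gene_b: str
    method: str
    stratum: str    # "variant" / "nonvariant"
    r: float
    p: float
    n: int
    defined: bool = True


def coexpression(gene_a: str, values_a: np.ndarray,
                 gene_b: str, values_b: np.ndarray,
                 variant_mask: np.ndarray) -> list[CorrelationResult]:
    """Kendall/Pearson/Spearman correlation of two genes in each stratum."""
    fns = {"pearson": stats.pearsonr,
           "spearman": stats.spearmanr,
           "kendall": stats.kendalltau}
    variant_mask = np.asarray(variant_mask, dtype=bool)
    ya = log2p1(values_a)
    yb = log2p1(values_b)
    out: list[CorrelationResult] = []
    for stratum, mask in (("variant", variant_mask), ("nonvariant", ~variant_mask)):
        a, b = ya[mask], yb[mask]
        for method in COEXPR_METHODS:
            if a.size < 3 or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
                out.append(CorrelationResult(gene_a, gene_b, method, stratum,
                                             float("nan"), float("nan"),
                                             int(a.size), False))
                continue
            res = fns[method](a, b)
            out.append(CorrelationResult(gene_a, gene_b, method, stratum,
                                         float(res.statistic),
                                         float(res.pvalue), int(a.size)))
    return out


@dataclass
class AucResult:
    gene_id: str
    task: str
    auc: float
    n: int


def loo_auc(feature, labels, gene_id: str = "", task: str = "") -> AucResult:
    """Leave-one-out cross-validated AUC of a one-feature linear classifier.

    Per fold, the decision rule is the class-mean midpoint on the training
    samples: the held-out decision value is the sample's signed offset from
    the midpoint along the feature axis. Held-out values are pooled and
    scored with the Mann-Whitney AUC. Orientation follows the raw feature
    (a marker whose positive class sits lower scores below 0.5), so
    AUC(feature) + AUC(-feature) = 1 on tie-free data.
    """
    x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    n = x.size
    if n < 4:
        raise DataError("loo_auc: need n >= 4")
    if y.all() or not y.any():
        raise DataError("loo_auc: both classes must be present")
    if y.sum() < 2 or (~y).sum() < 2:
        raise DataError("loo_auc: each class needs >=2 samples")
    decisions = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        m1 = x[tr & y].mean()
        m0 = x[tr & ~y].mean()
        decisions[i] = x[i] - 0.5 * (m0 + m1)
    return AucResult(gene_id, task, float(roc_auc_score(y, decisions)), n)


def de_table(results: list[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.contrast, r.n0, r.n1, r.effect, r.t, r.p, r.testable)
         for r in results],
        columns=["gene_id", "contrast", "n0", "n1", "effect", "t", "p", "testable"])


def coexpression_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_a, r.gene_b, r.method, r.stratum, r.n, r.r, r.p, r.defined)
         for r in results],
        columns=["gene_a", "gene_b", "method", "stratum", "n", "r", "p", "defined"])


def auc_table(results: list[AucResult]) -> pd.DataFrame:
    return pd.DataFrame([(r.gene_id, r.task, r.n, r.auc) for r in results],
                        columns=["gene_id", "task", "n", "auc"])
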