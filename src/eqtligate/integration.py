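"""Gene-set over-representation of candidate + known causal genes, the
disease-related co-occurrence filter, and the final risk-SNP /
susceptibility-gene selection.

A functional category is *disease-related* when it is significantly
over-represented (hypergeometric upper tail, BH-FDR < threshold) in the
query set (candidate genes united with known causal genes) AND contains at
least one gene of each kind — the co-occurrence rule. Susceptibility genes
are candidate genes sitting in a disease-related category whose own
candidate SNP is association-significant; those SNPs are the risk SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult
from .data_model import (
    MISSING,
    DataError,
    GeneSetCollection,
    GenotypeMatrix,
    KnownCausalGenes,
    SampleTable,
    SnpGeneMap,
)
from .eqtl import AnovaResult, CandidateSet, LinearFit, bh_adjust

logger = logging.getLogger("eqtligate")


@dataclass
class EnrichmentRecord:
    category_id: str
    name: str
    k: int          # query genes in category
    K: int          # category size within the universe
    n_query: int
    N: int          # universe size
    p: float
    q: float
    overlap_candidates: frozenset[str]
    overlap_known: frozenset[str]
    disease_related: bool


def gene_share_percent(n_final: int, n_algorithm: int) -> int:
    """Final-candidate share of one eQTL algorithm's gene yield, as the
    integer percentage used in funnel summaries."""
    if n_algorithm <= 0:
        raise DataError("gene_share_percent: algorithm gene count must be positive")
    return round(100.0 * n_final / n_algorithm)


def hypergeom_overrep(k: int, K: int, n_query: int, N: int) -> float:
    """Upper-tail over-representation p-value, P[X >= k],
    X ~ Hypergeometric(N, K, n_query)."""
    if not (0 <= k <= min(K, n_query) <= N) or K > N:
        raise DataError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n_query}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n_query))


def run_enrichment(candidates: set[str],
                   known: KnownCausalGenes,
                   sets: GeneSetCollection,
                   universe: set[str],
                   fdr: float = 0.05) -> list[EnrichmentRecord]:
    """Over-representation of (candidates | known) across all categories.

    Query genes outside the universe are dropped with a warning; category
    membership is likewise intersected with the universe. Categories with
    no query overlap (k = 0) are not tested.
    """
    query = set(candidates) | set(known.genes)
    if not query:
        raise DataError("enrichment: empty query gene set")
    outside = query - universe
    if outside:
        logger.warning("enrichment: %d query genes outside the universe dropped",
                       len(outside))
        query -= outside
    if not query:
        raise DataError("enrichment: no query genes inside the universe")
    N = len(universe)
    n_query = len(query)
    records: list[EnrichmentRecord] = []
    for cid in sorted(sets.sets):
        members = set(sets.sets[cid]) & universe
        hit = query & members
        if not hit:
            continue
        p = hypergeom_overrep(len(hit), len(members), n_query, N)
        records.append(EnrichmentRecord(
            cid, sets.names.get(cid, cid), len(hit), len(members), n_query, N,
            p, float("nan"),
            frozenset(hit & set(candidates)), frozenset(hit & set(known.genes)),
            False))
    qs = bh_adjust([r.p for r in records])
    for r, q in zip(records, qs):
        r.q = float(q)
        r.disease_related = bool(
            q < fdr and r.overlap_candidates and r.overlap_known)
    return records


@dataclass
class SusceptibilityReport:
    """Final selection, one row per (gene, risk SNP) with per-stage evidence."""

    table: pd.DataFrame  # gene_id, snp_id, chrom, pos, variant counts, evidence

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene_id"])

    @property
    def snps(self) -> set[str]:
        return set(self.table["snp_id"])


def variant_counts(codes: np.ndarray, samples: SampleTable) -> tuple[int, int]:
    """(n_variant_normal, n_variant_disease): samples carrying >=1 ALT allele."""
    carrier = (codes != MISSING) & (codes >= 1)
    disease = samples.disease_mask
    return int(carrier[~disease].sum()), int(carrier[disease].sum())


def finalize(candidates: CandidateSet,
             enrich: list[EnrichmentRecord],
             assoc: list[AssociationResult],
             snp_map: SnpGeneMap,
             gm: GenotypeMatrix,
             samples: SampleTable,
             anova_results: list[AnovaResult] | None = None,
             linreg_results: list[LinearFit] | None = None) -> SusceptibilityReport:
    """Select susceptibility genes and risk SNPs.

    A candidate gene qualifies when (i) it belongs to at least one
    disease-related category and (ii) at least one of ITS candidate SNPs is
    association-significant; that SNP becomes a risk SNP.
    """
    disease_cats = [r for r in enrich if r.disease_related]
    cooccurring = set().union(*(r.overlap_candidates for r in disease_cats)) \
        if disease_cats else set()
    assoc_by_id = {a.snp_id: a for a in assoc}
    anova_q = {}
    for r in anova_results or []:
        if np.isfinite(r.q):
            anova_q[r.snp_id] = min(r.q, anova_q.get(r.snp_id, np.inf))
    linreg_q = {f.snp_id: f.q for f in linreg_results or []}
    cat_of_gene: dict[str, EnrichmentRecord] = {}
    for r in sorted(disease_cats, key=lambda r: r.q):
        for g in r.overlap_candidates:
            cat_of_gene.setdefault(g, r)

    rows = []
    for snp in sorted(candidates.candidate_snps):
        gene = snp_map.gene_of(snp)
        if gene not in cooccurring:
            continue
        a = assoc_by_id.get(snp)
        if a is None or not a.significant:
            continue
        rec = gm.record(snp)
        n_var_normal, n_var_disease = variant_counts(gm.row(snp), samples)
        cat = cat_of_gene[gene]
        rows.append((gene, snp, rec.chrom, rec.pos, n_var_normal, n_var_disease,
                     a.p, anova_q.get(snp, float("nan")),
                     linreg_q.get(snp, float("nan")), cat.category_id, cat.q))
    table = pd.DataFrame(rows, columns=[
        "gene_id", "snp_id", "chrom", "pos",
        "n_variant_normal", "n_variant_disease",
        "assoc_p", "anova_q", "linreg_q", "category_id", "category_q"])
    if table.empty:
        logger.warning("finalize: no susceptibility genes survived all stages")
    return SusceptibilityReport(table)


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.category_id, r.name, r.k, r.K, r.n_query, r.N, r.p, r.q,
          r.disease_related,
          ";".join(sorted(r.overlap_candidates)),
          ";".join(sorted(r.overlap_known))) for r in records],
        columns=["category_id", "name", "k", "K", "n_query", "N", "p", "q",
                 "disease_related", "overlap_candidates", "overlap_known"])
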