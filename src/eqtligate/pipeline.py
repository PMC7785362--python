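"""End-to-end orchestration: QC -> association || dual eQTL -> enrichment
co-occurrence -> final selection -> validation battery, with a stage-count
funnel and fully deterministic outputs.

Candidate SNPs (HWE p >= 0.05 in controls, MAF >= 0.1) form the shared
universe for both the association and eQTL branches; the stricter HWE
threshold (0.001) applies inside the association stage only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association as assoc_mod
from . import eqtl as eqtl_mod
from . import integration as integ_mod
from . import validation as valid_mod
from .data_model import (
    DataError,
    filter_expressed_genes,
    validate_alignment,
)
from .synthetic_data import Cohort, SimulationConfig, read_cohort, simulate_cohort
from .variant_filtering import qc_table, select_candidates

logger = logging.getLogger("eqtligate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Every tunable threshold and flag of a run, plus the input source."""

    input_dir: str | None = None            # cohort bundle on disk ...
    simulate: SimulationConfig | None = None  # ... or simulate in-process
    hwe_candidate_alpha: float = 0.05
    hwe_assoc_alpha: float = 0.001
    maf_min: float = 0.1
    assoc_alpha: float = 5e-8
    anova_fdr: float = 0.05
    linreg_fdr: float = 1e-6
    enrich_fdr: float = 0.05
    de_alpha: float = 0.05
    expr_min_value: float = 0.5
    expr_min_fraction: float = 0.30
    assoc_test: str = "allelic"             # or "genotypic"
    anova_stratification_a: str = eqtl_mod.STRAT_CARRIERS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hwe_candidate_alpha", "hwe_assoc_alpha", "maf_min",
                     "assoc_alpha", "anova_fdr", "linreg_fdr", "enrich_fdr",
                     "de_alpha", "expr_min_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DataError(f"{name} must lie in (0,1), got {v}")
        if self.input_dir is None and self.simulate is None:
            raise DataError("config needs either input_dir or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise DataError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
        if isinstance(raw.get("simulate"), dict):
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        cfg = cls(**raw)
        if seed is not None:
            cfg.seed = seed
            if cfg.simulate is not None:
                cfg.simulate = dataclasses.replace(cfg.simulate, seed=seed)
        return cfg

    def thresholds(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("input_dir")
        d.pop("simulate")
        return d


@dataclass
class StageFunnel:
    """Counts at every stage of the evidence funnel."""

    n_snps: int = 0
    n_candidate_snps: int = 0
    n_assoc_significant: int = 0
    n_anova_pass: int = 0
    n_linreg_pass: int = 0
    n_candidate_risk_snps: int = 0
    n_candidate_genes: int = 0
    n_disease_categories: int = 0
    n_cooccurring_genes: int = 0
    n_risk_snps: int = 0
    n_susceptibility_genes: int = 0

    def assert_containment(self) -> None:
        assert self.n_candidate_snps <= self.n_snps
        assert self.n_assoc_significant <= self.n_candidate_snps
        assert self.n_candidate_risk_snps <= min(self.n_anova_pass, self.n_linreg_pass)
        assert self.n_candidate_genes <= self.n_candidate_risk_snps or \
            self.n_candidate_risk_snps == 0
        assert self.n_cooccurring_genes <= self.n_candidate_genes
        assert self.n_susceptibility_genes <= self.n_cooccurring_genes
        assert self.n_risk_snps <= self.n_candidate_risk_snps

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    report: integ_mod.SusceptibilityReport
    funnel: StageFunnel
    tables: dict = field(default_factory=dict)  # name -> DataFrame


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (AssertionError, PipelineError):
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def load_inputs(config: PipelineConfig) -> Cohort:
    if config.simulate is not None:
        return simulate_cohort(config.simulate)
    return read_cohort(config.input_dir)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; optionally write all result tables to ``out_dir``."""
    cohort = _stage("load")(load_inputs)(config)
    gm, expr, samples = cohort.genotypes, cohort.expression, cohort.samples
    snp_map, gene_sets, known = cohort.snp_gene_map, cohort.gene_sets, cohort.known_genes
    _stage("validate")(validate_alignment)(gm, expr, samples, snp_map)

    expr_f = _stage("expression_filter")(filter_expressed_genes)(
        expr, config.expr_min_value, config.expr_min_fraction)

    qc = _stage("variant_qc")(select_candidates)(
        gm, config.hwe_candidate_alpha, config.maf_min, samples)
    candidate_qc = [q for q in qc if q.is_candidate]
    candidate_ids = {q.snp_id for q in candidate_qc}

    assoc = _stage("association")(assoc_mod.run_association)(
        gm, samples, candidate_qc, config.hwe_assoc_alpha, config.maf_min,
        config.assoc_alpha, config.assoc_test)
    significant_snps = {a.snp_id for a in assoc if a.significant}

    anova = _stage("anova_eqtl")(eqtl_mod.run_anova_eqtl)(
        gm, expr_f, samples, snp_map, config.anova_fdr, candidate_ids,
        config.anova_stratification_a)
    anova_pass = eqtl_mod.anova_pass_set(anova, config.anova_fdr)
    linreg = _stage("linreg_eqtl")(eqtl_mod.run_linreg_eqtl)(
        gm, expr_f, samples, snp_map, config.linreg_fdr, candidate_ids)
    linreg_pass = eqtl_mod.linreg_pass_set(linreg, config.linreg_fdr)
    candidates = eqtl_mod.intersect_algorithms(anova_pass, linreg_pass, snp_map)

    universe = set(expr_f.gene_ids)
    if candidates.candidate_genes or known.genes:
        enrich = _stage("enrichment")(integ_mod.run_enrichment)(
            candidates.candidate_genes, known, gene_sets, universe,
            config.enrich_fdr)
    else:
        enrich = []
    report = _stage("finalize")(integ_mod.finalize)(
        candidates, enrich, assoc, snp_map, gm, samples, anova, linreg)

    de_results, coexpr_results, auc_results = _stage("validation")(
        _validation_battery)(report, cohort, enrich)

    disease_cats = [r for r in enrich if r.disease_related]
    cooccurring = set().union(*(r.overlap_candidates for r in disease_cats)) \
        if disease_cats else set()
    funnel = StageFunnel(
        n_snps=len(gm.snps),
        n_candidate_snps=len(candidate_ids),
        n_assoc_significant=len(significant_snps),
        n_anova_pass=len(anova_pass),
        n_linreg_pass=len(linreg_pass),
        n_candidate_risk_snps=len(candidates.candidate_snps),
        n_candidate_genes=len(candidates.candidate_genes),
        n_disease_categories=len(disease_cats),
        n_cooccurring_genes=len(cooccurring),
        n_risk_snps=len(report.snps),
        n_susceptibility_genes=len(report.genes),
    )
    funnel.assert_containment()

    tables = {
        "qc": qc_table(qc),
        "association": assoc_mod.association_table(assoc, gm),
        "anova_eqtl": eqtl_mod.anova_table(anova),
        "linreg_eqtl": eqtl_mod.linreg_table(linreg),
        "enrichment": integ_mod.enrichment_table(enrich),
        "susceptibility": report.table,
        "de_validation": valid_mod.de_table(de_results),
        "coexpression": valid_mod.coexpression_table(coexpr_results),
        "auc": valid_mod.auc_table(auc_results),
    }
    result = PipelineResult(report, funnel, tables)
    if out_dir is not None:
        write_outputs(result, config, Path(out_dir))
    return result


def _validation_battery(report, cohort: Cohort, enrich):
    """DE contrasts, coexpression-with-known-partner and LOO-AUC per report row."""
    gm, expr, samples = cohort.genotypes, cohort.expression, cohort.samples
    disease = samples.disease_mask
    de_results, coexpr_results, auc_results = [], [], []
    cat_known = {r.category_id: sorted(r.overlap_known) for r in enrich}
    for row in report.table.itertuples():
        gene, snp = row.gene_id, row.snp_id
        if gene not in expr:
            continue
        values = expr.row(gene)
        codes = gm.row(snp)
        de_results.extend(valid_mod.de_battery(gene, values, codes, disease))
        called = codes != -1
        variant = called & (codes >= 1)
        partners = cat_known.get(row.category_id, [])
        if partners and partners[0] in expr:
            coexpr_results.extend(valid_mod.coexpression(
                gene, values, partners[0], expr.row(partners[0]), variant))
        feat = np.asarray(values, dtype=np.float64)
        tasks = (
            (valid_mod.CONTRAST_VARIANT_ALL, feat[called], variant[called]),
            (valid_mod.CONTRAST_VARIANT_DISEASE,
             feat[called & disease], variant[called & disease]),
            (valid_mod.CONTRAST_DISEASE, feat, disease),
        )
        for task, x, y in tasks:
            if y.sum() >= 2 and (~y).sum() >= 2:
                auc_results.append(valid_mod.loo_auc(x, y, gene, task))
    return de_results, coexpr_results, auc_results


def write_outputs(result: PipelineResult, config: PipelineConfig,
                  out_dir: Path) -> None:
    """Write every stage table as TSV plus funnel and threshold metadata JSON."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    with open(out_dir / "funnel.json", "w") as fh:
        json.dump(result.funnel.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    meta = {"thresholds": config.thresholds(),
            "expression_transform": "log2(value + 1) inside statistical tests"}
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
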