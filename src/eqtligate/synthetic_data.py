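"""Planted-truth case/control cohort simulator.

Generates genotype, expression, phenotype, cis-map, gene-set and known-gene
bundles with a known answer key, so every pipeline stage — and the
end-to-end recovery test — runs without any external download.

Model
-----
* Null SNPs: one ALT-allele frequency per SNP drawn uniformly from
  ``maf_range``; genotypes sampled genotype-wise under Hardy-Weinberg
  proportions (p^2, 2pq, q^2), identically in cases and controls.
* Planted SNPs: HWE within each phenotype, but at ``planted_case_alt_freq``
  in disease samples and ``planted_control_alt_freq`` in normal samples —
  the case/control frequency gap is the planted association signal.
* HWE violators (optional): genotypes drawn with heterozygote deficit via
  an inbreeding coefficient F (p^2+Fpq, 2pq(1-F), q^2+Fpq).
* Expression: per-gene baseline drawn from ``baseline_range`` (FPKM-like
  units). A planted gene g mapped to planted SNP s follows
  baseline + eqtl_beta * genotype + disease_shift * 1[disease] + N(0, noise_sd);
  null genes and known causal genes are baseline + N(0, noise_sd),
  independent of both genotype and phenotype. Values are clipped at 0.
* Categories: each planted gene is co-placed with known causal genes in a
  functional category (so the co-occurrence filter, not expression signal,
  is what links candidates to known genes); remaining categories hold known
  or null genes only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data_model import (
    DISEASE,
    NORMAL,
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    KnownCausalGenes,
    SampleTable,
    SnpGeneMap,
    SnpRecord,
    read_expression,
    read_gene_sets,
    read_known_genes,
    read_samples,
    read_snp_gene_map,
    read_vcf_genotypes,
    write_expression,
    write_gene_sets,
    write_known_genes,
    write_samples,
    write_snp_gene_map,
    write_vcf_genotypes,
)

#: known causal genes co-placed with each planted gene in its category
_KNOWN_PER_CATEGORY = 4


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated cohort; defaults mirror the study's shape."""

    n_disease: int = 98
    n_normal: int = 91
    n_snps: int = 2000
    n_genes: int = 1000
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_planted: int = 5
    planted_case_alt_freq: float = 0.55
    planted_control_alt_freq: float = 0.25
    eqtl_beta: float = 2.0          # FPKM per ALT allele
    disease_shift: float = 2.0      # FPKM added in disease samples of planted genes
    noise_sd: float = 0.5           # FPKM
    n_categories: int = 20
    category_size: int = 10
    n_known_genes: int = 32
    n_hwe_violators: int = 0
    hwe_inbreeding: float = 0.8
    baseline_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_snps:
            raise DataError("n_planted exceeds n_snps")
        if self.n_planted + self.n_hwe_violators > self.n_snps:
            raise DataError("planted + HWE-violating SNPs exceed n_snps")
        for f in (self.planted_case_alt_freq, self.planted_control_alt_freq):
            if not 0.0 < f < 1.0:
                raise DataError("planted allele frequencies must lie in (0,1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise DataError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.n_genes < self.n_planted + self.n_known_genes:
            raise DataError("n_genes too small for planted + known genes")
        if self.n_planted > 0 and self.n_known_genes > 0 and self.category_size < 2:
            raise DataError("category_size < 2 cannot co-place planted and known genes")
        if self.n_planted > 0 and self.n_categories < 1:
            raise DataError("need at least one category to place planted genes")


def paper_shape(seed: int = 0, **overrides) -> SimulationConfig:
    """Cohort with the study's sample arithmetic: 98 disease + 91 normal."""
    return replace(SimulationConfig(seed=seed), **overrides)


def power_shape(seed: int = 0, **overrides) -> SimulationConfig:
    """Larger balanced cohort (300/300) used for planted-truth recovery."""
    cfg = SimulationConfig(
        n_disease=300, n_normal=300, n_snps=500, n_genes=600,
        n_planted=5, seed=seed,
    )
    return replace(cfg, **overrides)


def null_shape(seed: int = 0, **overrides) -> SimulationConfig:
    """All-null cohort (no planted effects) for calibration checks."""
    cfg = SimulationConfig(
        n_disease=300, n_normal=300, n_snps=2000, n_genes=1000,
        n_planted=0, seed=seed,
    )
    return replace(cfg, **overrides)


PRESETS = {"paper-shape": paper_shape, "power-shape": power_shape, "null": null_shape}


@dataclass
class TruthSet:
    """Answer key of a simulated cohort."""

    planted_snp_ids: frozenset[str]
    planted_gene_ids: frozenset[str]
    effects: dict[str, tuple[float, float]]  # snp_id -> (allele-freq gap, eqtl beta)


@dataclass
class Cohort:
    """A complete simulated dataset plus its answer key (None when read from disk)."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    samples: SampleTable
    snp_gene_map: SnpGeneMap
    gene_sets: GeneSetCollection
    known_genes: KnownCausalGenes
    truth: TruthSet | None = None


def sample_genotypes_hwe(alt_freq: float, n: int, rng: np.random.Generator,
                         inbreeding: float = 0.0) -> np.ndarray:
    """Draw additive genotype codes under HWE (optionally with inbreeding F)."""
    q = alt_freq
    p = 1.0 - q
    f = inbreeding
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    probs /= probs.sum()
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full bundle deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_disease + config.n_normal

    sample_ids = ([f"D{i + 1:04d}" for i in range(config.n_disease)]
                  + [f"N{i + 1:04d}" for i in range(config.n_normal)])
    phenotypes = [DISEASE] * config.n_disease + [NORMAL] * config.n_normal
    samples = SampleTable(sample_ids, phenotypes)
    disease_mask = samples.disease_mask

    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    planted_genes = gene_ids[: config.n_planted]
    known = gene_ids[config.n_planted: config.n_planted + config.n_known_genes]
    null_genes = gene_ids[config.n_planted + config.n_known_genes:]

    # --- genotypes ---------------------------------------------------------
    snps: list[SnpRecord] = []
    codes = np.empty((config.n_snps, n_total), dtype=np.int8)
    mapping: dict[str, str] = {}
    effects: dict[str, tuple[float, float]] = {}
    planted_snps: list[str] = []
    for i in range(config.n_snps):
        snp_id = f"snp{i + 1:05d}"
        snps.append(SnpRecord(snp_id, "1", 1000 * (i + 1), "A", "G"))
        if i < config.n_planted:
            row = np.empty(n_total, dtype=np.int8)
            row[disease_mask] = sample_genotypes_hwe(
                config.planted_case_alt_freq, config.n_disease, rng)
            row[~disease_mask] = sample_genotypes_hwe(
                config.planted_control_alt_freq, config.n_normal, rng)
            planted_snps.append(snp_id)
            mapping[snp_id] = planted_genes[i]
            effects[snp_id] = (
                config.planted_case_alt_freq - config.planted_control_alt_freq,
                config.eqtl_beta,
            )
        else:
            freq = rng.uniform(*config.maf_range)
            f = (config.hwe_inbreeding
                 if i < config.n_planted + config.n_hwe_violators else 0.0)
            row = sample_genotypes_hwe(freq, n_total, rng, inbreeding=f)
            if null_genes:
                mapping[snp_id] = null_genes[(i - config.n_planted) % len(null_genes)]
        codes[i] = row
    gm = GenotypeMatrix(snps, sample_ids, codes)

    # --- expression --------------------------------------------------------
    baselines = rng.uniform(*config.baseline_range, size=config.n_genes)
    values = baselines[:, None] + rng.normal(0.0, config.noise_sd,
                                             size=(config.n_genes, n_total))
    for j, gene in enumerate(planted_genes):
        geno = codes[j].astype(np.float64)
        values[j] += config.eqtl_beta * geno
        values[j] += config.disease_shift * disease_mask
    np.clip(values, 0.0, None, out=values)
    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    # --- functional categories ---------------------------------------------
    names: dict[str, str] = {}
    sets: dict[str, frozenset[str]] = {}
    fill_pool = null_genes if null_genes else gene_ids
    for c in range(config.n_categories):
        cid = f"cat{c + 1:03d}"
        members: list[str] = []
        if c < config.n_planted:
            # disease-style category: one planted gene + known causal genes
            members.append(planted_genes[c])
            if known:
                k = min(_KNOWN_PER_CATEGORY, len(known))
                members.extend(known[(c * k + j) % len(known)] for j in range(k))
            members = list(dict.fromkeys(members))
        elif known and c < config.n_planted + 2:
            # known-only categories exercise the co-occurrence rule
            members.extend(known[j % len(known)] for j in range(min(5, len(known))))
            members = list(dict.fromkeys(members))
        n_fill = max(config.category_size - len(members), 0)
        if n_fill and fill_pool:
            pick = rng.choice(len(fill_pool), size=min(n_fill, len(fill_pool)),
                              replace=False)
            members.extend(fill_pool[int(j)] for j in sorted(pick))
        members = list(dict.fromkeys(members))
        if not members:
            members = [fill_pool[0]]
        names[cid] = f"synthetic category {c + 1}"
        sets[cid] = frozenset(members)
    gene_sets = GeneSetCollection(names, sets)

    truth = TruthSet(frozenset(planted_snps), frozenset(planted_genes), effects)
    return Cohort(gm, expr, samples, SnpGeneMap(mapping), gene_sets,
                  KnownCausalGenes(frozenset(known)), truth)


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

BUNDLE_FILES = ("cohort.vcf", "expression.tsv", "samples.tsv",
                "snp_gene_map.tsv", "categories.gmt", "known_genes.txt", "truth.tsv")


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike, force: bool = False) -> Path:
    """Write the bundle; refuses to overwrite an existing bundle unless ``force``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [f for f in BUNDLE_FILES if (out / f).exists()]
    if existing and not force:
        raise FileExistsError(
            f"{out} already holds a cohort bundle ({existing[0]} ...); use force=True")
    write_vcf_genotypes(cohort.genotypes, out / "cohort.vcf")
    write_expression(cohort.expression, out / "expression.tsv")
    write_samples(cohort.samples, out / "samples.tsv")
    write_snp_gene_map(cohort.snp_gene_map, out / "snp_gene_map.tsv")
    write_gene_sets(cohort.gene_sets, out / "categories.gmt")
    write_known_genes(cohort.known_genes, out / "known_genes.txt")
    if cohort.truth is not None:
        with open(out / "truth.tsv", "w") as fh:
            fh.write("snp_id\tgene_id\tfreq_gap\teqtl_beta\n")
            for snp in sorted(cohort.truth.planted_snp_ids):
                gap, beta = cohort.truth.effects[snp]
                gene = cohort.snp_gene_map.gene_of(snp)
                fh.write(f"{snp}\t{gene}\t{gap:g}\t{beta:g}\n")
    return out


def read_cohort(bundle_dir: str | os.PathLike) -> Cohort:
    """Read a bundle written by :func:`write_cohort` (truth.tsv optional)."""
    d = Path(bundle_dir)
    truth = None
    truth_path = d / "truth.tsv"
    if truth_path.exists():
        import pandas as pd

        df = pd.read_csv(truth_path, sep="\t", dtype={"snp_id": str, "gene_id": str})
        truth = TruthSet(
            frozenset(df["snp_id"]),
            frozenset(df["gene_id"]),
            {r.snp_id: (float(r.freq_gap), float(r.eqtl_beta))
             for r in df.itertuples()},
        )
    return Cohort(
        read_vcf_genotypes(d / "cohort.vcf"),
        read_expression(d / "expression.tsv"),
        read_samples(d / "samples.tsv"),
        read_snp_gene_map(d / "snp_gene_map.tsv"),
        read_gene_sets(d / "categories.gmt"),
        read_known_genes(d / "known_genes.txt"),
        truth,
    )
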