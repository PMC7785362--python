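"""Core domain containers and readers/writers for the on-disk formats.

The pipeline works on five aligned inputs: a biallelic genotype matrix
(SNPs x samples, additive ALT-allele codes), a nonnegative expression
matrix (genes x samples, FPKM-like units), a sample phenotype table
(disease/normal), a SNP-to-gene cis map, gene-set annotations (GMT) and a
list of known causal genes. Everything downstream assumes these objects
have been validated and sample-aligned here.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("eqtligate")

#: sentinel for a missing genotype call
MISSING: int = -1

DISEASE = "disease"
NORMAL = "normal"
PHENOTYPES = (DISEASE, NORMAL)


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP site (1-based VCF position convention)."""

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"SNP {self.snp_id}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"SNP {self.snp_id}: REF and ALT alleles are identical")


@dataclass
class GenotypeMatrix:
    """Additive genotype codes: 0 = wild-type, 1 = het, 2 = hom-ALT, -1 = missing."""

    snps: list[SnpRecord]
    sample_ids: list[str]
    codes: np.ndarray  # (n_snps, n_samples) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.snps), len(self.sample_ids)):
            raise DataError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise DataError("genotype codes must be in {0,1,2} or missing (-1)")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate SNP ids in genotype matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in genotype matrix")
        self._row = {sid: i for i, sid in enumerate(ids)}

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def row(self, snp_id: str) -> np.ndarray:
        return self.codes[self._row[snp_id]]

    def record(self, snp_id: str) -> SnpRecord:
        return self.snps[self._row[snp_id]]


@dataclass
class ExpressionMatrix:
    """Nonnegative abundance values (FPKM-like), genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_genes, n_samples) float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("expression matrix dims inconsistent with ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids in expression matrix")
        if (self.values < 0).any():
            raise DataError("expression values must be nonnegative")
        self._row = {g: i for i, g in enumerate(self.gene_ids)}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._row[gene_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleTable:
    """Per-sample phenotype labels (disease / normal)."""

    sample_ids: list[str]
    phenotypes: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.phenotypes):
            raise DataError("sample table: ids and phenotypes differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in sample table")
        bad = sorted({p for p in self.phenotypes if p not in PHENOTYPES})
        if bad:
            raise DataError(f"unknown phenotype labels {bad}; expected {PHENOTYPES}")

    @property
    def disease_mask(self) -> np.ndarray:
        return np.array([p == DISEASE for p in self.phenotypes], dtype=bool)

    @property
    def n_disease(self) -> int:
        return int(self.disease_mask.sum())

    @property
    def n_normal(self) -> int:
        return len(self.sample_ids) - self.n_disease


@dataclass
class SnpGeneMap:
    """cis map: each SNP points to the gene whose functional element hosts it."""

    mapping: dict[str, str]

    def gene_of(self, snp_id: str) -> str | None:
        return self.mapping.get(snp_id)


@dataclass
class GeneSetCollection:
    """Functional categories (GO/KEGG-style), keyed by category id."""

    names: dict[str, str]
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cid, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene-set category {cid} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class KnownCausalGenes:
    """Genes pre-annotated as disease-linked (drives the co-occurrence filter)."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    """Read GT fields of a biallelic VCF into additive codes.

    Multiallelic records are rejected; missing calls become -1.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib raises bare OSError on malformed input
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise DataError(f"VCF {path} declares no samples")
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise DataError(
                f"VCF {path}, record {i + 1} ({var.CHROM}:{var.POS}): "
                f"multiallelic site (ALT={var.ALT}); split or drop it upstream"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(snp_id, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        codes = np.asarray(var.gt_types, dtype=np.int8)
        codes[codes == 3] = MISSING  # gts012: 3 == unknown
        rows.append(codes)
    if not snps:
        raise DataError(f"VCF {path} contains no variant records")
    return GenotypeMatrix(snps, sample_ids, np.vstack(rows))


def write_vcf_genotypes(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype columns."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(rec.chrom for rec in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for rec, row in zip(gm.snps, gm.codes):
            calls = "\t".join(gt[int(c)] for c in row)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise DataError(f"duplicate gene ids in {path}")
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)),
                            df.to_numpy(dtype=np.float64))


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_samples(path: str | os.PathLike) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "phenotype"} <= set(df.columns):
        raise DataError(f"{path}: expected columns sample_id, phenotype")
    return SampleTable(list(df["sample_id"]), list(df["phenotype"]))


def write_samples(samples: SampleTable, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample_id": samples.sample_ids,
                  "phenotype": samples.phenotypes}).to_csv(path, sep="\t", index=False)


def read_snp_gene_map(path: str | os.PathLike) -> SnpGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "gene_id"} <= set(df.columns):
        raise DataError(f"{path}: expected columns snp_id, gene_id")
    if df["snp_id"].duplicated().any():
        raise DataError(f"{path}: a SNP maps to more than one gene")
    if (df["gene_id"].str.strip() == "").any():
        raise DataError(f"{path}: empty gene id")
    return SnpGeneMap(dict(zip(df["snp_id"], df["gene_id"])))


def write_snp_gene_map(snp_map: SnpGeneMap, path: str | os.PathLike) -> None:
    pd.DataFrame(sorted(snp_map.mapping.items()),
                 columns=["snp_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | os.PathLike) -> GeneSetCollection:
    """Read GMT: category <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    names: dict[str, str] = {}
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path} line {lineno}: GMT needs id, description, >=1 gene")
            cid = parts[0]
            if cid in sets:
                raise DataError(f"{path} line {lineno}: duplicate category id {cid}")
            names[cid] = parts[1]
            sets[cid] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(names, sets)


def write_gene_sets(gsc: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for cid in sorted(gsc.sets):
            genes = "\t".join(sorted(gsc.sets[cid]))
            fh.write(f"{cid}\t{gsc.names.get(cid, cid)}\t{genes}\n")


def read_known_genes(path: str | os.PathLike) -> KnownCausalGenes:
    with open(path) as fh:
        genes = frozenset(line.strip() for line in fh if line.strip())
    if not genes:
        raise DataError(f"{path}: known causal gene list is empty")
    return KnownCausalGenes(genes)


def write_known_genes(known: KnownCausalGenes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(known.genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# expression-level gene filter & helpers
# ---------------------------------------------------------------------------

def filter_expressed_genes(expr: ExpressionMatrix,
                           min_value: float = 0.5,
                           min_fraction: float = 0.30) -> ExpressionMatrix:
    """Keep genes expressed above ``min_value`` in at least ``min_fraction`` of samples.

    A gene survives iff strictly more than ``min_value`` in at least
    ``ceil(min_fraction * n_samples)`` samples ("greater than 0.5 in at
    least 30% of the samples" convention).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise DataError(f"min_fraction must be in [0,1], got {min_fraction}")
    need = math.ceil(min_fraction * len(expr.sample_ids))
    counts = (expr.values > min_value).sum(axis=1)
    keep = counts >= need
    if not keep.any():
        logger.warning("expression filter removed every gene")
    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(kept_ids, list(expr.sample_ids), expr.values[keep])


def log2p1(values: np.ndarray) -> np.ndarray:
    """log2(x + 1) — the variance-stabilising transform used by the statistics."""
    return np.log2(np.asarray(values, dtype=np.float64) + 1.0)


def validate_alignment(gm: GenotypeMatrix,
                       expr: ExpressionMatrix,
                       samples: SampleTable,
                       snp_map: SnpGeneMap | None = None) -> None:
    """Check sample alignment (and optionally the cis map) before any statistics."""
    if gm.sample_ids != samples.sample_ids:
        raise DataError("genotype matrix and sample table disagree on sample order/ids")
    if expr.sample_ids != samples.sample_ids:
        raise DataError("expression matrix and sample table disagree on sample order/ids")
    if snp_map is not None:
        unknown = set(snp_map.mapping) - set(gm.snp_ids)
        if unknown:
            raise DataError(f"SNP-gene map references unknown SNPs, e.g. {sorted(unknown)[:3]}")
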