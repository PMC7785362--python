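"""Case/control SNP association: per-SNP allelic chi-square with a fixed
genome-wide significance threshold.

The default test is the 1-df Pearson chi-square on the 2x2 table of allele
counts (ALT/REF x case/control), without continuity correction — the
behaviour of PLINK's basic ``--assoc``. A genotypic 2-df variant (chi-square
on the 3x2 genotype-count table) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, GenotypeMatrix, SampleTable
from .variant_filtering import SnpQc, genotype_counts

logger = logging.getLogger("eqtligate")

GENOME_WIDE_ALPHA = 5e-8


@dataclass
class AssociationResult:
    snp_id: str
    chrom: str
    pos: int
    case_alt: int
    case_ref: int
    control_alt: int
    control_ref: int
    chi2: float
    p: float
    significant: bool
    degenerate: bool = False


def _pearson_chi2(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square for an r x c count table; no continuity correction."""
    table = np.asarray(table, dtype=np.float64)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 1.0, True
    expected = np.outer(row, col) / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df=df)), False


def allelic_chisq(case_counts: tuple[int, int, int],
                  control_counts: tuple[int, int, int]) -> dict:
    """Allelic 2x2 chi-square from per-group genotype counts.

    Returns a dict with the allele table, chi2, p and a ``degenerate`` flag
    (set when a table margin is zero, e.g. a cohort-monomorphic SNP; p = 1
    by convention).
    """
    c0, c1, c2 = case_counts
    k0, k1, k2 = control_counts
    if c0 + c1 + c2 < 1 or k0 + k1 + k2 < 1:
        raise DataError("allelic_chisq: each group needs >=1 non-missing sample")
    case_alt = c1 + 2 * c2
    case_ref = 2 * c0 + c1
    control_alt = k1 + 2 * k2
    control_ref = 2 * k0 + k1
    table = np.array([[case_alt, case_ref], [control_alt, control_ref]])
    chi2, p, degenerate = _pearson_chi2(table)
    return {
        "case_alt": case_alt, "case_ref": case_ref,
        "control_alt": control_alt, "control_ref": control_ref,
        "chi2": chi2, "p": p, "degenerate": degenerate,
    }


def genotypic_chisq(case_counts: tuple[int, int, int],
                    control_counts: tuple[int, int, int]) -> dict:
    """Genotypic 2-df chi-square (genotype x phenotype 3x2 table)."""
    table = np.array([case_counts, control_counts], dtype=np.float64)
    # drop genotype columns absent from both groups; df shrinks accordingly
    table = table[:, table.sum(axis=0) > 0]
    chi2, p, degenerate = _pearson_chi2(table)
    return {"chi2": chi2, "p": p, "degenerate": degenerate}


def run_association(gm: GenotypeMatrix,
                    samples: SampleTable,
                    qc: list[SnpQc],
                    hwe_alpha: float = 0.001,
                    maf_min: float = 0.1,
                    alpha: float = GENOME_WIDE_ALPHA,
                    test: str = "allelic") -> list[AssociationResult]:
    """Test SNPs passing HWE(``hwe_alpha``) and MAF(``maf_min``) filters.

    ``significant`` marks p < ``alpha`` (fixed genome-wide threshold, no
    FDR at this stage). Results are sorted by (chrom, pos).
    """
    if test not in ("allelic", "genotypic"):
        raise DataError(f"unknown association test {test!r}")
    if samples.sample_ids != gm.sample_ids:
        raise DataError("sample table misaligned with genotype matrix")
    disease = samples.disease_mask
    qc_by_id = {q.snp_id: q for q in qc}

    results: list[AssociationResult] = []
    for rec, row in zip(gm.snps, gm.codes):
        q = qc_by_id.get(rec.snp_id)
        if q is None or not np.isfinite(q.maf):
            continue
        if q.maf < maf_min or not (q.hwe_p >= hwe_alpha):
            continue
        case_counts = genotype_counts(row[disease])
        control_counts = genotype_counts(row[~disease])
        if sum(case_counts) == 0 or sum(control_counts) == 0:
            continue
        al = allelic_chisq(case_counts, control_counts)
        if test == "genotypic":
            g = genotypic_chisq(case_counts, control_counts)
            chi2, p, degen = g["chi2"], g["p"], g["degenerate"]
        else:
            chi2, p, degen = al["chi2"], al["p"], al["degenerate"]
        results.append(AssociationResult(
            rec.snp_id, rec.chrom, rec.pos,
            al["case_alt"], al["case_ref"], al["control_alt"], al["control_ref"],
            chi2, p, bool(p < alpha), degen,
        ))
    if not results:
        logger.warning("association: no testable SNPs after QC filters")

    def _chrom_key(r: AssociationResult):
        return (0, int(r.chrom)) if r.chrom.isdigit() else (1, r.chrom)

    results.sort(key=lambda r: (_chrom_key(r), r.pos))
    return results


def association_table(results: list[AssociationResult],
                      gm: GenotypeMatrix) -> pd.DataFrame:
    """Association results as a tidy frame (Chr/SNP/Position/Ref/Alt/p layout)."""
    rows = []
    for r in results:
        rec = gm.record(r.snp_id)
        rows.append((rec.chrom, r.snp_id, rec.pos, rec.ref, rec.alt,
                     r.case_alt, r.case_ref, r.control_alt, r.control_ref,
                     r.chi2, r.p, r.significant))
    return pd.DataFrame(rows, columns=[
        "chrom", "snp_id", "pos", "ref", "alt",
        "case_alt", "case_ref", "control_alt", "control_ref",
        "chi2", "p", "significant"])
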