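"""Per-SNP QC: Hardy-Weinberg equilibrium testing, minor-allele frequency,
and candidate-SNP selection.

HWE departure is tested with the classical 1-df goodness-of-fit chi-square
on the three genotype counts against p^2 / 2pq / q^2 expectations. When a
phenotype table is supplied, HWE is evaluated in control (normal) samples
only — the convention of case/control QC, since a true disease association
shifts pooled genotype frequencies away from HWE (Wahlund effect) even when
each stratum is in equilibrium. Without phenotypes the pooled cohort is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MISSING, DataError, GenotypeMatrix, SampleTable

logger = logging.getLogger("eqtligate")


@dataclass
class SnpQc:
    """QC summary for one SNP (counts over non-missing samples)."""

    snp_id: str
    n0: int
    n1: int
    n2: int
    maf: float
    hwe_chi2: float
    hwe_p: float
    is_candidate: bool
    reason: str = ""  # empty when candidate; else "maf" / "hwe" / "missing" / "monomorphic"


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """Count (n0, n1, n2) over non-missing entries of one genotype row."""
    ok = codes != MISSING
    vals = codes[ok]
    return int((vals == 0).sum()), int((vals == 1).sum()), int((vals == 2).sum())


def compute_maf(n0: int, n1: int, n2: int) -> float:
    """Folded minor-allele frequency from genotype counts."""
    n = n0 + n1 + n2
    if n < 1:
        raise DataError("compute_maf: no non-missing genotypes")
    alt = (n1 + 2 * n2) / (2 * n)
    return min(alt, 1.0 - alt)


def hwe_chisq_test(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-square test of HWE from genotype counts.

    Returns (chi2, p). Monomorphic counts are rejected — callers exclude
    those via the MAF filter first.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise DataError("hwe_chisq_test: no non-missing genotypes")
    alt = (n1 + 2 * n2) / (2 * n)
    if alt <= 0.0 or alt >= 1.0:
        raise DataError("hwe_chisq_test: monomorphic SNP has no HWE expectation")
    p = 1.0 - alt
    expected = np.array([n * p * p, 2 * n * p * alt, n * alt * alt])
    observed = np.array([n0, n1, n2], dtype=np.float64)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def select_candidates(gm: GenotypeMatrix,
                      hwe_alpha: float = 0.05,
                      maf_min: float = 0.1,
                      samples: SampleTable | None = None,
                      max_missing: float = 0.10) -> list[SnpQc]:
    """QC every SNP; candidates have HWE p >= ``hwe_alpha`` and MAF >= ``maf_min``.

    ``samples``, when given, restricts the HWE test to normal samples (see
    module docstring); MAF is always computed on the whole cohort. SNPs with
    more than ``max_missing`` missing calls are dropped with a warning.
    """
    if not 0.0 < hwe_alpha < 1.0:
        raise DataError(f"hwe_alpha must be in (0,1), got {hwe_alpha}")
    control_mask = None
    if samples is not None:
        if samples.sample_ids != gm.sample_ids:
            raise DataError("sample table misaligned with genotype matrix")
        control_mask = ~samples.disease_mask
        if not control_mask.any():
            control_mask = None  # no controls: fall back to pooled HWE

    out: list[SnpQc] = []
    n_samples = len(gm.sample_ids)
    for rec, row in zip(gm.snps, gm.codes):
        n0, n1, n2 = genotype_counts(row)
        n_called = n0 + n1 + n2
        if n_called == 0 or (n_samples - n_called) / n_samples > max_missing:
            logger.warning("SNP %s dropped: >%d%% missing genotypes",
                           rec.snp_id, int(max_missing * 100))
            out.append(SnpQc(rec.snp_id, n0, n1, n2, float("nan"),
                             float("nan"), float("nan"), False, "missing"))
            continue
        maf = compute_maf(n0, n1, n2)
        if maf == 0.0:
            out.append(SnpQc(rec.snp_id, n0, n1, n2, 0.0,
                             float("nan"), float("nan"), False, "monomorphic"))
            continue
        h0, h1, h2 = (genotype_counts(row[control_mask])
                      if control_mask is not None else (n0, n1, n2))
        halt = h1 + 2 * h2
        if h0 + h1 + h2 == 0 or halt == 0 or halt == 2 * (h0 + h1 + h2):
            # polymorphic overall but monomorphic in controls: HWE untestable,
            # treated as passing (no evidence of departure)
            chi2, hp = 0.0, 1.0
        else:
            chi2, hp = hwe_chisq_test(h0, h1, h2)
        if maf < maf_min:
            out.append(SnpQc(rec.snp_id, n0, n1, n2, maf, chi2, hp, False, "maf"))
        elif hp < hwe_alpha:
            out.append(SnpQc(rec.snp_id, n0, n1, n2, maf, chi2, hp, False, "hwe"))
        else:
            out.append(SnpQc(rec.snp_id, n0, n1, n2, maf, chi2, hp, True))
    return out


def qc_table(qcs: list[SnpQc]) -> pd.DataFrame:
    """QC results as a tidy frame (the on-disk TSV layout)."""
    return pd.DataFrame(
        {
            "snp_id": [q.snp_id for q in qcs],
            "n0": [q.n0 for q in qcs],
            "n1": [q.n1 for q in qcs],
            "n2": [q.n2 for q in qcs],
            "maf": [q.maf for q in qcs],
            "hwe_chi2": [q.hwe_chi2 for q in qcs],
            "hwe_p": [q.hwe_p for q in qcs],
            "is_candidate": [q.is_candidate for q in qcs],
            "reason": [q.reason for q in qcs],
        }
    )
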