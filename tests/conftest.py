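import pytest

from eqtligate.synthetic_data import (
    SimulationConfig,
    null_shape,
    power_shape,
    simulate_cohort,
)

PLANTED_GENES = {"g0001", "g0002", "g0003", "g0004", "g0005"}
PLANTED_SNPS = {"snp00001", "snp00002", "snp00003", "snp00004", "snp00005"}


@pytest.fixture(scope="session")
def power_cohort():
    """Balanced 300/300 cohort with 5 planted risk SNPs among 500."""
    return simulate_cohort(power_shape(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """All-null 300/300 cohort with 2000 SNPs for calibration checks."""
    return simulate_cohort(null_shape(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for I/O and plumbing tests."""
    cfg = SimulationConfig(n_disease=30, n_normal=30, n_snps=20, n_genes=60,
                           n_planted=2, n_categories=5, seed=5)
    return simulate_cohort(cfg)
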