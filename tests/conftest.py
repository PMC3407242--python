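import numpy as np
import pandas as pd
import pytest

from breedline.genotypes import GenotypeMatrix, PopulationLabels, SnpMap
from breedline.simulate import DriftConfig, simulate_balding_nichols


def make_snp_map(n, chrom="1", alleles=("A", "G")):
    return SnpMap(
        pd.DataFrame(
            {
                "snp_id": [f"snp{i}" for i in range(n)],
                "chromosome": [chrom] * n,
                "position_bp": np.arange(1, n + 1) * 1000,
                "allele_a": [alleles[0]] * n,
                "allele_b": [alleles[1]] * n,
            }
        )
    )


def make_genotypes(codes, sample_prefix="s", snp_map=None):
    codes = np.asarray(codes, dtype=np.int8)
    n_samples, n_snps = codes.shape
    snp_map = snp_map or make_snp_map(n_snps)
    samples = [f"{sample_prefix}{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, snp_map, codes)


@pytest.fixture
def two_pop_panel():
    """Two drifted populations (c=0.06 each), 2,000 SNPs, 40 diploids each."""
    cfg = DriftConfig(
        n_pops=2,
        drift_c=[0.06, 0.06],
        n_snps=2000,
        samples_per_pop=[40, 40],
        seed=42,
    )
    return simulate_balding_nichols(cfg)


@pytest.fixture
def small_noisy_panel():
    """Small panel with missingness for QC / pairwise-complete paths."""
    cfg = DriftConfig(
        n_pops=2,
        drift_c=[0.05, 0.05],
        n_snps=300,
        samples_per_pop=[15, 15],
        missing_rate=0.05,
        seed=9,
    )
    return simulate_balding_nichols(cfg)
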