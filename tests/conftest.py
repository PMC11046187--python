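import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None, database=None)
settings.load_profile("default")

from penmate.plink_io import SnpMeta
from penmate.synthetic_data import RiskLocus, SimConfig, generate


@pytest.fixture(scope="session")
def small_matrix():
    """40 pairs x 120 null SNPs, mild missingness and within-pair correlation."""
    cfg = SimConfig(
        n_pairs=40,
        n_null_snps=120,
        within_pair_corr=0.1,
        missing_rate=0.02,
        seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def spiked_matrix():
    """102 pairs with three strong recessive risk loci among 800 null SNPs."""
    loci = [
        RiskLocus(chrom=7, pos_bp=90_845_941, maf=0.4, model="two_copy", theta=8.0, snp_id="spikeA"),
        RiskLocus(chrom=3, pos_bp=84_578_325, maf=0.35, model="two_copy", theta=8.0, snp_id="spikeB"),
        RiskLocus(chrom=12, pos_bp=10_000_000, maf=0.45, model="two_copy", theta=8.0, snp_id="spikeC"),
    ]
    cfg = SimConfig(
        n_pairs=102, n_null_snps=800, risk_loci=loci,
        within_pair_corr=0.05, missing_rate=0.01, seed=7,
    )
    return generate(cfg)


@pytest.fixture
def snp_ag():
    return SnpMeta(chrom=7, pos_bp=90_845_941, snp_id="snpAG", a1="A", a2="G")
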