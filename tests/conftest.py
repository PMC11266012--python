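import numpy as np
import pytest

from mrkit.harmonize import harmonized_set_from_arrays
from mrkit.sumstats import SummaryStatRecord, SummaryStatTable


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                beta=0.1, se=0.01, pval=1e-9, eaf=0.3, n=10000.0):
    return SummaryStatRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, eaf=eaf, n=n,
    )


def make_table(records, name="trait"):
    return SummaryStatTable(trait_name=name, records=list(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20240710)


@pytest.fixture
def proportional_hset():
    """Noiseless beta_out = 0.5 * beta_exp: every estimator must return 0.5."""
    beta_exp = np.array([0.1, 0.2, 0.15, 0.3, 0.25, 0.12, 0.18, 0.22, 0.27, 0.11])
    return harmonized_set_from_arrays(
        beta_exp, np.full(10, 0.01), 0.5 * beta_exp, np.full(10, 0.02)
    )


@pytest.fixture
def noisy_hset(rng):
    """30 strong instruments, true effect 0.3, modest outcome noise."""
    k = 30
    beta_exp = rng.normal(0.2, 0.05, k)
    se_exp = np.full(k, 0.005)
    se_out = rng.uniform(0.01, 0.03, k)
    beta_out = 0.3 * beta_exp + rng.normal(0, se_out)
    return harmonized_set_from_arrays(rng.normal(beta_exp, se_exp), se_exp, beta_out, se_out)
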