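import logging

import numpy as np
import pytest

from mrscan import (AssociationRecord, HarmonizedPair, HarmonizedSet,
                    SummaryStatsSet)

logging.getLogger("mrscan").setLevel(logging.WARNING)


def make_record(snp_id="rs1", chrom="1", pos=1000, effect_allele="A",
                other_allele="G", beta=0.1, se=0.01, pval=1e-10, eaf=0.3,
                n=10_000):
    return AssociationRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                             effect_allele=effect_allele,
                             other_allele=other_allele, beta=beta, se=se,
                             pval=pval, eaf=eaf, n=n)


def make_set(records, role="exposure", trait_id="trait"):
    return SummaryStatsSet(trait_id, role, records)


def make_harmonized(beta_exp, beta_out, se_exp=None, se_out=None, n_exp=None,
                    n_out=None):
    """HarmonizedSet straight from effect arrays (all pairs aligned)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    J = len(beta_exp)
    se_exp = np.full(J, 0.01) if se_exp is None else np.asarray(se_exp, float)
    se_out = np.full(J, 0.01) if se_out is None else np.asarray(se_out, float)
    pairs = [
        HarmonizedPair(snp_id=f"rs{j + 1}", beta_exp=float(beta_exp[j]),
                       se_exp=float(se_exp[j]), beta_out=float(beta_out[j]),
                       se_out=float(se_out[j]), eaf_exp=0.3, eaf_out=0.3,
                       action="aligned", n_exp=n_exp, n_out=n_out)
        for j in range(J)
    ]
    return HarmonizedSet(pairs)


@pytest.fixture
def simple_harmonized():
    """Three instruments sharing the exact ratio 0.5."""
    return make_harmonized([0.1, 0.2, 0.3], [0.05, 0.1, 0.15])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
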