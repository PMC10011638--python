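import numpy as np
import pytest

from tsmr import (
    HarmonizedRecord,
    HarmonizedSet,
    RatioEstimate,
    SummaryStatSet,
    VariantAssociation,
)


def make_variant(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.02, pval=1e-9,
                 chrom="1", pos=1_000_000, eaf=0.3, n=50_000.0):
    return VariantAssociation(rsid=rsid, effect_allele=ea, other_allele=oa,
                              beta=beta, se=se, pval=pval, chrom=chrom, pos=pos,
                              eaf=eaf, n=n)


def make_harmonized(beta_x, beta_y, se_y, se_x=0.01, prefix="rs"):
    """Build a HarmonizedSet of kept records from parallel arrays."""
    recs = [
        HarmonizedRecord(rsid=f"{prefix}{i + 1}", beta_x=float(bx), se_x=se_x,
                         beta_y=float(by), se_y=float(sy))
        for i, (bx, by, sy) in enumerate(zip(beta_x, beta_y, se_y))
    ]
    return HarmonizedSet(recs)


def random_ratios(rng, j=20):
    theta = rng.normal(0.2, 0.5, size=j)
    se = rng.uniform(0.05, 0.5, size=j)
    return [RatioEstimate(f"rs{i + 1}", float(t), float(s))
            for i, (t, s) in enumerate(zip(theta, se))]


def random_harmonized(rng, j=20):
    bx = rng.uniform(0.05, 0.3, size=j) * rng.choice([-1, 1], size=j)
    sy = rng.uniform(0.01, 0.05, size=j)
    by = 0.3 * bx + rng.normal(0, sy)
    return make_harmonized(bx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_sumstats():
    return SummaryStatSet(
        "trait", "continuous",
        [
            make_variant("rs1", beta=0.10, se=0.02, pval=1e-9, pos=1_000_000, eaf=0.3),
            make_variant("rs2", ea="C", oa="T", beta=-0.08, se=0.015, pval=1e-12,
                         pos=2_000_000, eaf=None),
            make_variant("rs3", ea="G", oa="A", beta=0.05, se=0.01, pval=3e-8,
                         chrom="2", pos=500_000, eaf=0.45, n=None),
            make_variant("rs4", ea="T", oa="C", beta=0.2, se=0.05, pval=0.2,
                         chrom="2", pos=900_000, eaf=0.1),
            make_variant("rs5", ea="A", oa="T", beta=0.12, se=0.03, pval=1e-10,
                         chrom="3", pos=700_000, eaf=0.2),
        ],
    )
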