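import numpy as np
import pytest

from gutmr.sumstats import HarmonizedInstrument, SummaryDataset, VariantAssociation


def make_instrument(
    variant_id="rs1", beta_exp=0.1, beta_out=0.02, se_out=0.01,
    se_exp=0.01, eaf_exp=0.3,
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=variant_id, beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out, eaf_exp=eaf_exp,
    )


def make_variant(
    variant_id="rs1", effect_allele="A", other_allele="G", eaf=0.3,
    beta=0.1, se=0.01, pvalue=1e-6, n=18_340, chrom=None, pos=None,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=variant_id, effect_allele=effect_allele,
        other_allele=other_allele, eaf=eaf, beta=beta, se=se,
        pvalue=pvalue, n=n, chrom=chrom, pos=pos,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_instruments(rng):
    """A reproducible 10-instrument set with mild heterogeneity."""
    hs = []
    for i in range(10):
        bx = rng.uniform(0.1, 0.5)
        hs.append(make_instrument(
            variant_id=f"rs{i + 1}",
            beta_exp=bx,
            beta_out=0.2 * bx + rng.normal(0, 0.01),
            se_out=rng.uniform(0.008, 0.02),
            se_exp=0.01,
            eaf_exp=rng.uniform(0.05, 0.95),
        ))
    return hs


@pytest.fixture
def small_dataset():
    return SummaryDataset(
        "taxon_a", "genus",
        [
            make_variant("rs1", eaf=0.3, beta=0.12, pvalue=1e-8,
                         chrom="1", pos=1_000_000),
            make_variant("rs2", eaf=0.4, beta=0.10, pvalue=1e-7,
                         chrom="1", pos=2_000_000),
            make_variant("rs3", eaf=0.2, beta=0.15, pvalue=1e-6,
                         chrom="2", pos=5_000_000),
        ],
    )
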