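import numpy as np
import pytest

from mrtarget.summary_data import (
    HarmonizedInstruments,
    HarmonizedVariant,
    SummaryDataset,
    VariantRecord,
)


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=1e-9,
    n=100_000,
):
    return VariantRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_dataset(records, trait_name="trait", trait_type="quantitative", n_total=None, n_cases=None):
    if n_total is None:
        n_total = max(r.n for r in records) if records else 1
    return SummaryDataset(
        trait_name=trait_name,
        trait_type=trait_type,
        records=list(records),
        n_total=n_total,
        n_cases=n_cases,
    )


def make_instruments(beta_exp, se_exp, beta_out, se_out):
    """Build HarmonizedInstruments directly from effect arrays."""
    variants = [
        HarmonizedVariant(
            variant_id=f"rs{j + 1}",
            beta_exp=float(bx),
            se_exp=float(sx),
            beta_out=float(by),
            se_out=float(sy),
            eaf_exp=0.3,
            eaf_out=0.3,
            action_taken="none",
        )
        for j, (bx, sx, by, sy) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]
    return HarmonizedInstruments(variants=variants)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def small_dataset():
    records = [
        make_record("rs1", pos=1_000_000, beta=0.10, se=0.02, pvalue=1e-10),
        make_record("rs2", pos=1_001_000, effect_allele="T", other_allele="C",
                    beta=-0.08, se=0.02, pvalue=1e-9),
        make_record("rs3", pos=1_002_000, effect_allele="A", other_allele="C",
                    beta=0.06, se=0.02, pvalue=1e-8),
    ]
    return make_dataset(records, trait_name="ldl")
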