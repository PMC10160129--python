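import numpy as np
import pandas as pd
import pytest

from mrkit import HarmonizedSet, SummaryTable


@pytest.fixture
def toy_set() -> HarmonizedSet:
    """Three instruments with a hand-checkable IVW slope of 330/725."""
    return HarmonizedSet.from_arrays(
        bx=[0.1, 0.2, 0.3],
        se_x=[0.01, 0.01, 0.01],
        by=[0.05, 0.08, 0.16],
        se_y=[0.01, 0.01, 0.02],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230504)


def random_harmonized_set(rng: np.random.Generator, J: int = 20) -> HarmonizedSet:
    """An arbitrary, well-conditioned instrument set for oracle comparisons."""
    bx = rng.normal(0.0, 0.05, J)
    bx[np.abs(bx) < 1e-3] = 1e-3
    return HarmonizedSet.from_arrays(
        bx=bx,
        se_x=rng.uniform(0.002, 0.01, J),
        by=rng.normal(0.3 * bx, 0.01),
        se_y=rng.uniform(0.005, 0.02, J),
    )


def make_table(
    snp_ids,
    effect_allele,
    other_allele,
    eaf,
    beta,
    se,
    pvalue=None,
    name="trait",
    trait_type="binary",
) -> SummaryTable:
    n = len(snp_ids)
    if pvalue is None:
        pvalue = [0.5] * n
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": pvalue,
        }
    )
    return SummaryTable(trait_name=name, data=df, trait_type=trait_type)
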