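import numpy as np
import pandas as pd
import pytest

from triploase import CrossDesign, default_design


@pytest.fixture(scope="session")
def design() -> CrossDesign:
    return default_design()


@pytest.fixture
def reciprocal_design() -> CrossDesign:
    """Minimal design with just the two reciprocal L2/L4 triploid crosses."""
    return CrossDesign(
        groups={
            "L4xL2": {"maternal": "L4", "paternal": "L2",
                      "samples": ["L4xL2_1", "L4xL2_2", "L4xL2_3"]},
            "L2xL4": {"maternal": "L2", "paternal": "L4",
                      "samples": ["L2xL4_1", "L2xL4_2", "L2xL4_3"]},
        },
        ploidy_of_parent={"L2": 2, "L4": 4},
    )


def binom_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Brute-force minimum-likelihood two-sided binomial P-value.

    Enumerates the full pmf and sums every outcome whose probability does
    not exceed the observed outcome's (with a small relative slack for
    floating-point ties, the standard convention for this statistic).
    """
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum()))


@pytest.fixture(scope="session")
def binom_oracle():
    return binom_two_sided_oracle


def make_allele_records(rows: list[tuple]) -> pd.DataFrame:
    """rows: (gene, chrom, pos, allele_a, allele_b, reads_a, reads_b, sample)"""
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos", "allele_a", "allele_b",
                 "reads_a", "reads_b", "sample"],
    )
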