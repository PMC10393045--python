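import numpy as np
import pandas as pd
import pytest

from tipselect.tip_matrix import GenotypeMatrix, ZygosityMatrix


def make_loci(n, chrom="chr1", spacing=1000, prefix="tip"):
    return pd.DataFrame({
        "id": [f"{prefix}_{i}" for i in range(n)],
        "chrom": chrom,
        "pos": spacing * np.arange(n),
        "te_family": "Stowaway",
        "te_order": "MITE",
    })


@pytest.fixture
def small_zygosity():
    """4 loci x 5 samples with known boundary values and one missing cell."""
    loci = make_loci(4)
    values = np.array([
        [0.10, 0.20, 0.24, 0.0, 0.0],   # peak 0.24 -> dropped at 0.25
        [0.25, 0.0, 0.0, 0.0, 0.0],     # boundary peak -> kept
        [0.9, 0.8, np.nan, 0.0, 0.049],  # missing cell, sub-cutoff value
        [1.0, 1.0, 1.0, 1.0, 1.0],
    ])
    return ZygosityMatrix(loci, [f"s{i}" for i in range(5)], values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_genotypes(n_loci, n_samples, rng, missing_frac=0.0):
    calls = (rng.random((n_loci, n_samples)) < rng.uniform(
        0.1, 0.9, size=(n_loci, 1))).astype(float)
    if missing_frac:
        calls[rng.random(calls.shape) < missing_frac] = np.nan
    return GenotypeMatrix(make_loci(n_loci), [f"s{i}" for i in range(n_samples)],
                          calls)
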