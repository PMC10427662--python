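import numpy as np
import pandas as pd
import pytest

from kernelscan.geno_io import GenotypeDataset, compute_variant_stats


def make_dataset(dosages, positions=None, chrom="1", sample_prefix="ind"):
    """Build a GenotypeDataset from a raw dosage array (int, -1 = missing)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = 1 + 1000 * np.arange(m)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "id": [f"v{j}" for j in range(m)],
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    variants = compute_variant_stats(dosages, variants)
    return GenotypeDataset(dosages, variants, [f"{sample_prefix}{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """3 samples x 2 variants, one missing call."""
    return make_dataset([[0, 2], [1, -1], [2, 1]])
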