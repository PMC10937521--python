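import numpy as np
import pandas as pd
import pytest

from fedgen.datatypes import GenotypeBlock, default_variant_table


def make_block(dosages, variant_ids=None) -> GenotypeBlock:
    """GenotypeBlock from a raw dosage array with autogenerated metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = default_variant_table(m)
    if variant_ids is not None:
        variants["variant_id"] = list(variant_ids)
    samples = pd.DataFrame({"sample_id": [f"s{i:04d}" for i in range(n)]})
    return GenotypeBlock(dosages, variants, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_block(rng):
    """A 40 x 30 block with common variants and a few missing calls."""
    freqs = rng.uniform(0.2, 0.8, 30)
    d = rng.binomial(2, freqs, size=(40, 30)).astype(np.int8)
    miss = rng.random(d.shape) < 0.02
    d[miss] = -1
    return make_block(d)
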