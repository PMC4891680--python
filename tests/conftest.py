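import numpy as np
import pytest

from cosnp.synth import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    spec = SyntheticSpec(seed=11, n_genes=30, codons_per_gene=120)
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
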