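import numpy as np
import pytest

from sixmanet import SyntheticSpec, generate, write_fixture


@pytest.fixture(scope="session")
def separable_dataset():
    """Motif-planted dataset with full signal: classes separable by design."""
    return generate(SyntheticSpec(n_pos=300, n_neg=300, signal_strength=1.0, seed=11))


@pytest.fixture(scope="session")
def null_dataset():
    """Both classes carry the motif with probability 1/2: exchangeable classes."""
    return generate(SyntheticSpec(n_pos=300, n_neg=300, signal_strength=0.5, seed=12))


@pytest.fixture()
def fasta_pair(tmp_path, separable_dataset):
    return write_fixture(separable_dataset, tmp_path)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
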