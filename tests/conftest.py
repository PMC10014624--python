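import numpy as np
import pytest

from enhancernet import NetworkConfig, SyntheticSpec, simulate


@pytest.fixture
def tiny_cfg():
    """A miniature architecture for fast structural/numerical tests."""
    return NetworkConfig(
        num_blocks=2,
        layers_per_block=1,
        growth_rate=2,
        attention_reduction=1,
        head_hidden_sizes=(4,),
        dropout_rate=0.0,
        dtype="float64",
        seed=0,
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-motif benchmark: 20+20 train, 8+8 test."""
    spec = SyntheticSpec(n_pos=20, n_neg=20, test_n_pos=8, test_n_neg=8, seed=7)
    train, test, manifest = simulate(spec)
    return spec, train, test, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length=200):
    return "".join(rng.choice(list("ACGT"), size=length))
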