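import numpy as np
import pytest

from dtifuse.encoders import ModalFeatureMatrix
from dtifuse.fusion import AttentionParams
from dtifuse.synthdata import gen_molecules


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def molecule_pool():
    """100 parseable synthetic SMILES shared across graph tests."""
    return gen_molecules(100, size_range=(3, 25), seed=11)


def random_attention_params(rng, d, d_att=None, n_heads=1):
    d_att = d_att or d
    return AttentionParams(
        W_Q=rng.normal(size=(d, d_att)), W_K=rng.normal(size=(d, d_att)),
        W_V=rng.normal(size=(d, d_att)), b_Q=rng.normal(size=d_att),
        b_K=rng.normal(size=d_att), b_V=rng.normal(size=d_att),
        n_heads=n_heads)


def random_modal(rng, L, d, masked_tail=0, modality="seq"):
    mask = np.ones(L, dtype=bool)
    if masked_tail:
        mask[L - masked_tail:] = False
    values = rng.normal(size=(L, d))
    values[~mask] = 0.0
    return ModalFeatureMatrix(values, mask, modality)
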