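import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hairpin3d.folding import FoldingConfig, fold_many
from hairpin3d.hairpin_io import SequenceRecord
from hairpin3d.synthetic import SynthConfig, make_corpus


def random_sequences(rng, count, min_len, max_len, prefix="r"):
    out = []
    for i in range(count):
        n = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        out.append(SequenceRecord(id=f"{prefix}{i}", sequence=seq))
    return out


@pytest.fixture(scope="session")
def small_corpus():
    """A 40+40 synthetic corpus with default generator settings."""
    return make_corpus(SynthConfig(n_pos=40, n_neg=40, seed=11))


@pytest.fixture(scope="session")
def folded_hairpins(small_corpus):
    pos, neg = small_corpus
    cfg = FoldingConfig()
    return fold_many(pos, cfg) + fold_many(neg, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
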