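import numpy as np
import pytest

import lexdrift as ld


@pytest.fixture(scope="session")
def eth():
    """The 10-word headless /ð/ sublexicon (frequencies 1..211)."""
    return ld.fixture_headless_eth()


@pytest.fixture(scope="session")
def flap_lexicon():
    """Synthetic flap-eligible sublexicon: 762 types, 236 hapax, max 2793."""
    return ld.generate_zipf_lexicon(ld.ZipfSpec(762, 236, 2793, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_state(lex, n_red, u=None):
    """GenerationState with given counts (u defaults to zeros)."""
    u = np.zeros(lex.n_types) if u is None else np.asarray(u, float)
    return ld.GenerationState(lex, u, np.asarray(n_red, dtype=np.int64))
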