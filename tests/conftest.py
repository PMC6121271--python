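import numpy as np
import pytest

import wave2vec as wv
from wave2vec.types import DeltaSeries, SymbolSequence


@pytest.fixture(scope="session")
def fitted_spec():
    """A base-64 quantizer fitted on a large pool of Gaussian deltas."""
    rng = np.random.default_rng(42)
    pool = DeltaSeries(deltas=rng.normal(0.3, 2.0, 20000), source_id="pool")
    return wv.fit_quantizer(pool, base_n=64)


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-motif dataset with its quantizer and encoded corpus."""
    cfg = wv.default_config(n_per_class=30, seed=7)
    dataset, manifest = wv.generate_dataset(cfg)
    spec = wv.fit_quantizer(
        [wv.delta_encode(s) for s in dataset.instances], base_n=16
    )
    seqs = [wv.encode_signal(s, spec) for s in dataset.instances]
    return cfg, dataset, manifest, spec, seqs


@pytest.fixture(scope="session")
def toy_corpus():
    """Tiny unlabeled corpus for embedding unit tests."""
    return [
        SymbolSequence("s0", list("ABCABCAB")),
        SymbolSequence("s1", list("BCABCABC")),
        SymbolSequence("s2", list("CABCABCA")),
    ]


def random_table(rng, tokens, dim=4):
    """A vector table with random Gaussian vectors, for classifier tests."""
    from wave2vec.embedding import Vocabulary, WaveVectorTable

    vocab = Vocabulary(
        symbols=list(tokens), counts={t: 1 for t in tokens}, min_frequency=1
    )
    return WaveVectorTable(
        vocabulary=vocab,
        vectors={t: rng.normal(size=dim) for t in tokens},
    )
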