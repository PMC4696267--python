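import numpy as np
import pytest

import irvscreen as iv


def random_bitsets(rng, n, n_bits=64, density=0.2):
    return [
        frozenset(int(i) for i in np.flatnonzero(rng.random(n_bits) < density))
        for _ in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_training_data(rng):
    """Seeded 20-molecule labeled fingerprint set with potency classes."""
    bitsets = random_bitsets(rng, 20)
    fps = iv.FingerprintCollection.from_bitsets(
        [f"m{i:02d}" for i in range(20)], bitsets, n_bits=64
    )
    labels = rng.integers(0, 2, 20)
    if labels.min() == labels.max():  # ensure both classes
        labels[0] = 1 - labels[0]
    potency = np.where(labels == 1, rng.integers(0, 3, 20), 3)
    return iv.TrainingData(fps, labels, potency)


@pytest.fixture(scope="session")
def small_corpus():
    """One clustered synthetic target, reused across read-only tests."""
    cfg = iv.SyntheticCorpusConfig(
        n_targets=1, actives_per_target=50, inactives_per_target=50,
        negative_pool_size=200, seed=7,
    )
    return iv.generate_corpus(cfg)
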