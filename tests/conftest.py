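import numpy as np
import pytest

from protgauss import embeddings, gaussian, simulate


def make_random_reps(rng: np.random.Generator, n: int, d: int, min_tokens: int = 3):
    """Gaussian representations of random feature matrices (shared d)."""
    reps = []
    for i in range(n):
        L = int(rng.integers(min_tokens, min_tokens + 20))
        X = embeddings.FeatureMatrix(parent_id=f"r{i}", rows=rng.standard_normal((L, d)))
        reps.append(gaussian.to_gaussian(X))
    return reps


@pytest.fixture(scope="session")
def small_planted():
    """A 40-sequence, 2-mode planted-motif dataset with its table."""
    cfg = simulate.SimConfig(seed=11, n_sequences=40, n_labels=2, d=10)
    return simulate.synthetic_labeled_dataset(cfg)


@pytest.fixture(scope="session")
def small_reps(small_planted):
    seqs, table, _ = small_planted
    return [gaussian.to_gaussian(embeddings.featurize(s, table, table.k)) for s in seqs]
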