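import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import linkdrp as lp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_linear():
    return lp.make_fixture("tiny-linear")


@pytest.fixture
def tied_weights():
    return lp.make_fixture("tied-weights")


@pytest.fixture
def planted_columns():
    return lp.make_fixture("planted-columns")


@pytest.fixture
def small_dataset():
    """A modest synthetic cohort shared across pipeline tests."""
    spec = lp.SyntheticSpec(p=40, q=12, n=10, n_informative=4, noise_sd=0.5, rng_seed=7)
    D, y, T, labels, truth = lp.generate(spec)
    return D, y, T, labels, truth


def brute_force_auc(scores, labels):
    """O(P*N) pairwise AUC oracle with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s in pos:
        for t in neg:
            total += 1.0 if s > t else (0.5 if s == t else 0.0)
    return total / (len(pos) * len(neg))
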