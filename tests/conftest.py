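import numpy as np
import pytest

import crfthread as ct


@pytest.fixture(scope="session")
def tuned_linear_scorer():
    """A linear scorer with fixed, hand-set weights used across tests that
    need a sensible (not trained) singleton signal."""
    sc = ct.LinearScorer()
    sc.w.value[:] = [1.0, 0.0, 0.1, 0.0, 0.3, 0.3, 0.3, 0.0, 0.2]
    sc.gap.value[:] = [-0.5, -0.5]
    return sc


@pytest.fixture(scope="session")
def small_fixture():
    """One deterministic medium-noise pair fixture shared across tests."""
    fold = ct.sample_fold(12, 42)
    return ct.make_pair(fold, mutation_rate=0.3, indel_rate=0.1, noise=0.1, seed=7)


def random_theta(rng, n1, n2, gap_scores=False):
    th = rng.normal(size=(n1, n2, 5))
    th[:, :, 3:] = 0.0
    if not gap_scores:
        # constant insertion penalties, like the scorers emit
        th[:, :, 1] = rng.normal()
        th[:, :, 2] = rng.normal()
    return th


def random_valid_alignment(rng, n1, n2):
    """Sample a uniformly-structured random valid alignment (not uniform over
    alignments; only used as a source of arbitrary valid paths)."""
    k = int(rng.integers(1, min(n1, n2) + 1))
    ti = np.sort(rng.choice(n1, size=k, replace=False))
    qj = np.sort(rng.choice(n2, size=k, replace=False))
    return ct.alignment_from_pairs(list(zip(ti, qj)), n1, n2)
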