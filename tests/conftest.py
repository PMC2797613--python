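import itertools

import numpy as np
import pytest

from songvar import ChainSpec, EffectSpec, make_transition_matrix


def exact_signflip_pvalue(differences: np.ndarray) -> float:
    """Exhaustive 2^n sign-flip p-value (inclusive two-tailed counting).

    Enumerates every sign assignment, takes the mean of the signed
    differences, and counts (inclusively, with a float-tie guard) how many
    null means are at least as far from the null-distribution mean as the
    observed mean.  Independent of the bootstrap implementation.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
    ms = signs @ d / n
    null_mean = ms.mean()
    obs = d.mean()
    return float(np.mean(np.abs(ms - null_mean) >= abs(obs - null_mean) - 1e-12))


@pytest.fixture
def fixed_motifs():
    """20 identical ABCDE motifs: a perfectly stereotyped song."""
    return [[1, 2, 3, 4, 5] for _ in range(20)]


@pytest.fixture
def mixture_model():
    """A 5-syllable mixture chain at epsilon 0.5 with its true entropy."""
    spec = ChainSpec(n_syllables=5, epsilon=0.5)
    model, h = make_transition_matrix(spec)
    return spec, model, h


@pytest.fixture
def small_effect_spec():
    """A reduced paired design for fast end-to-end tests."""
    return EffectSpec(n_birds=5, eps_ns=0.2, eps_ud=0.4, eps_sd=0.05)
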