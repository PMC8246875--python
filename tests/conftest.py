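"""Shared fixtures: small seeded surveys and cached expensive fits."""

import numpy as np
import pytest

import ipoqll as q


@pytest.fixture(scope="session")
def penalties():
    return q.PenaltyConfig()


@pytest.fixture(scope="session")
def small_survey():
    """A 60x4 three-category survey sampled from a known GPCM."""
    theta = q.ability_grid(60, -2.5, 2.5)
    beta = [np.array([-0.5, 0.5])] * 4
    alpha = np.array([0.8, 1.0, 1.2, 1.5])
    rm = q.sample_gpcm(theta, beta, alpha, seed=11)
    return rm, q.GPCMParams(theta, beta, alpha)


@pytest.fixture(scope="session")
def inhomogeneous_survey():
    """The polytomous inhomogeneous design (301x18), one fixed seed."""
    return q.make_inhomogeneous(n_categories=5, seed=1)


@pytest.fixture(scope="session")
def inhomogeneous_full_fit(inhomogeneous_survey, penalties):
    """Joint fit of the full 18-item inhomogeneous survey (reused widely)."""
    return q.fit_included(inhomogeneous_survey.responses, range(18), penalties)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
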