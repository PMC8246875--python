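"""Seeded generators for the validation survey designs.

Three designs, each with 301 subjects and items grouped in 6-item
subsets, dichotomous (2-category) or polytomous (5-category):

* *inhomogeneous* — one ability dimension, three subsets with widely
  different discrimination blocks (hard / intermediate / easy to
  predict), 18 items;
* *multidimensional* — three subsets each driven by its own ability
  vector (the first an even grid on [-3, 3], the others independent
  permutations of it), equal discriminations, 18 items;
* *correlated* — two polytomous subsets (12 items) driven by two ability
  vectors within [-4, 4] with a prescribed Pearson correlation.

Thresholds are evenly spaced and centered (dichotomous beta = 0;
5-category beta = (-1.5, -.5, .5, 1.5)), and all responses are drawn
independently from the GPCM.  Every generator is a pure function of its
arguments including the seed (NumPy PCG64 streams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .containers import GPCMParams, ResponseMatrix

#: discrimination blocks of the inhomogeneous design (subsets 1-3)
INHOMOGENEOUS_ALPHA = np.array(
    [0.04, 0.045, 0.05, 0.055, 0.06, 0.065,
     0.2, 0.25, 0.3, 0.35, 0.4, 0.45,
     2.6, 2.65, 2.7, 2.75, 2.8, 2.85])

DEFAULT_N_SUBJECTS = 301
SUBSET_SIZE = 6


@dataclass
class SimulatedSurvey:
    """A simulated survey plus the ground truth that generated it."""

    responses: ResponseMatrix
    abilities: np.ndarray      # (n_dimensions, N) ability vector per dimension
    item_dimension: np.ndarray  # (P,) index of the dimension driving each item
    beta: list
    alpha: np.ndarray
    kind: str
    seed: int

    @property
    def subset_labels(self) -> np.ndarray:
        return self.item_dimension

    @property
    def true_params(self) -> GPCMParams:
        """Ground truth as GPCMParams (theta is the first dimension)."""
        return GPCMParams(self.abilities[0], self.beta, self.alpha)


def ability_grid(n: int = DEFAULT_N_SUBJECTS, low: float = -3.0,
                 high: float = 3.0) -> np.ndarray:
    """Evenly spaced abilities spanning [low, high]."""
    return np.linspace(low, high, n)


def default_thresholds(n_categories: int) -> np.ndarray:
    """Evenly spaced, centered thresholds with unit step."""
    m = n_categories - 1
    if m < 1:
        raise ValueError("need at least two categories")
    return np.arange(m) - (m - 1) / 2.0


def _draw_responses(theta_cells, beta, alpha, rng) -> np.ndarray:
    """Sample one response per cell; theta may vary per (subject, item)."""
    n, p = theta_cells.shape
    m = np.array([len(b) for b in beta])
    k_max = int(m.max())
    b_cum = np.zeros((p, k_max + 1))
    for i, b in enumerate(beta):
        b_cum[i, 1: m[i] + 1] = np.cumsum(b)
        b_cum[i, m[i] + 1:] = np.inf  # invalid categories get probability 0
    k = np.arange(k_max + 1)
    s = alpha[None, :, None] * (k[None, None, :] * theta_cells[:, :, None]
                                - b_cum[None, :, :])
    s[np.isnan(s)] = -np.inf
    s = np.where(np.isinf(b_cum[None, :, :]), -np.inf, s)
    probs = np.exp(s - logsumexp(s, axis=2, keepdims=True))
    cdf = np.cumsum(probs, axis=2)
    u = rng.random((n, p))
    return (u[:, :, None] > cdf[:, :, :-1]).sum(axis=2)


def sample_gpcm(theta, beta, alpha, seed: int = 0) -> ResponseMatrix:
    """Draw a response matrix from the GPCM, one cell per subject-item."""
    theta = np.asarray(theta, float)
    alpha = np.asarray(alpha, float)
    beta = [np.atleast_1d(np.asarray(b, float)) for b in beta]
    rng = np.random.default_rng(seed)
    values = _draw_responses(np.repeat(theta[:, None], len(beta), axis=1),
                             beta, alpha, rng)
    n_cat = np.array([len(b) + 1 for b in beta])
    return ResponseMatrix(values, n_cat)


def _finish(values, beta, abilities, item_dimension, alpha, kind, seed):
    n_cat = np.array([len(b) + 1 for b in beta])
    rm = ResponseMatrix(values, n_cat)
    return SimulatedSurvey(rm, abilities, np.asarray(item_dimension), beta,
                           np.asarray(alpha, float), kind, seed)


def make_inhomogeneous(n_categories: int = 5, seed: int = 0,
                       n_subjects: int = DEFAULT_N_SUBJECTS) -> SimulatedSurvey:
    """Single-dimension survey with three discrimination blocks.

    18 items; alpha follows :data:`INHOMOGENEOUS_ALPHA`, so subset 1
    (items 1-6) is nearly unpredictable noise and subset 3 (items 13-18)
    is highly predictive.
    """
    rng = np.random.default_rng(seed)
    theta = ability_grid(n_subjects)
    alpha = INHOMOGENEOUS_ALPHA.copy()
    beta = [default_thresholds(n_categories) for _ in alpha]
    theta_cells = np.repeat(theta[:, None], len(alpha), axis=1)
    values = _draw_responses(theta_cells, beta, alpha, rng)
    return _finish(values, beta, theta[None, :], np.zeros(len(alpha), int),
                   alpha, "inhomogeneous", seed)


def make_multidimensional(n_categories: int = 5, seed: int = 0,
                          n_subjects: int = DEFAULT_N_SUBJECTS) -> SimulatedSurvey:
    """Three 6-item subsets, each driven by its own (uncorrelated) ability.

    The first dimension is the even grid on [-3, 3]; the other two are
    independent random permutations of it, so the three ability vectors
    share their marginal distribution but are mutually decorrelated.
    Discriminations are all 1 (standard PCM items).
    """
    rng = np.random.default_rng(seed)
    base = ability_grid(n_subjects)
    abilities = np.stack([base, rng.permutation(base), rng.permutation(base)])
    item_dimension = np.repeat(np.arange(3), SUBSET_SIZE)
    alpha = np.ones(3 * SUBSET_SIZE)
    beta = [default_thresholds(n_categories) for _ in alpha]
    theta_cells = abilities[item_dimension, :].T  # (N, P)
    values = _draw_responses(theta_cells, beta, alpha, rng)
    return _finish(values, beta, abilities, item_dimension, alpha,
                   "multidimensional", seed)


def make_correlated(rho: float, seed: int = 0, n_categories: int = 5,
                    n_subjects: int = DEFAULT_N_SUBJECTS,
                    tol: float = 0.02, max_tries: int = 200) -> SimulatedSurvey:
    """Two polytomous 6-item subsets with correlated ability dimensions.

    Ability pairs are bivariate normal with correlation ``rho``, then
    linearly mapped (per dimension) onto [-4, 4]; the affine map leaves
    the Pearson correlation unchanged.  Draws are repeated until the
    empirical correlation is within ``tol`` of the target.
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("rho must lie strictly between -1 and 1")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    for _ in range(max_tries):
        raw = rng.multivariate_normal(np.zeros(2), cov, size=n_subjects,
                                      method="cholesky").T
        if abs(np.corrcoef(raw)[0, 1] - rho) <= tol:
            break
    else:
        raise RuntimeError(f"could not reach |corr - {rho}| <= {tol} "
                           f"in {max_tries} draws")
    lo, hi = -4.0, 4.0
    abilities = np.empty_like(raw)
    for d in range(2):
        x = raw[d]
        abilities[d] = lo + (hi - lo) * (x - x.min()) / (x.max() - x.min())
    item_dimension = np.repeat(np.arange(2), SUBSET_SIZE)
    alpha = np.ones(2 * SUBSET_SIZE)
    beta = [default_thresholds(n_categories) for _ in alpha]
    theta_cells = abilities[item_dimension, :].T
    values = _draw_responses(theta_cells, beta, alpha, rng)
    return _finish(values, beta, abilities, item_dimension, alpha,
                   "correlated", seed)
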