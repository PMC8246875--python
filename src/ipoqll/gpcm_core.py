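"""The GPCM probability model, itemset log likelihood and penalized objective.

The generalized partial credit model gives subject n probability

    P(X_ni = x) = exp(alpha_i * sum_{j<=x} (theta_n - beta_ij)) / D_ni,
    D_ni = 1 + sum_{k=1}^{m_i} exp(alpha_i * sum_{j<=k} (theta_n - beta_ij)),

of responding in category x of item i.  With alpha_i = 1 this is the
partial credit model; dichotomous items (m_i = 1) give the two-parameter
logistic model, and alpha_i = 1 with m_i = 1 the original Rasch model.

The penalized objective adds ridge terms that resolve the translation /
scale non-identifiability of joint maximum likelihood and keep estimates
finite for perfect or zero scores:

    F_S = L_S - lambda_theta * sum_n theta_n^2 - lambda_alpha * sum_{i in S} (ln alpha_i)^2.
"""

from __future__ import annotations

import numpy as np

from . import _core
from .containers import GPCMParams, ResponseMatrix


def _validate_itemset(itemset, n_items):
    items = np.asarray(list(itemset), dtype=np.int64)
    if items.size and (items.min() < 0 or items.max() >= n_items):
        raise IndexError(f"itemset index out of range 0..{n_items - 1}")
    if len(np.unique(items)) != items.size:
        raise ValueError("itemset contains duplicate indices")
    return items


def category_probabilities(theta_n: float, beta_i, alpha_i: float) -> np.ndarray:
    """Probabilities of the ``m_i + 1`` response categories of one item.

    Computed on the log scale with max-subtraction, so large
    ``|alpha * (theta - beta)|`` does not overflow.
    """
    beta_i = np.atleast_1d(np.asarray(beta_i, dtype=float))
    if beta_i.size < 1:
        raise ValueError("beta_i needs at least one threshold")
    if not (np.isfinite(theta_n) and np.isfinite(alpha_i) and np.all(np.isfinite(beta_i))):
        raise ValueError("non-finite GPCM parameter")
    if alpha_i <= 0:
        raise ValueError("alpha_i must be strictly positive")
    beta_pad, m = _core.pad_beta([beta_i])
    logp = _core.log_category_probs(np.array([float(theta_n)]), beta_pad,
                                    np.array([float(alpha_i)]), m)
    return np.exp(logp[0, 0])


def itemset_loglik(responses: ResponseMatrix, itemset, params: GPCMParams) -> float:
    """Log likelihood L_S of the responses on the given items.

    ``params`` must describe all items of ``responses``; missing cells
    contribute nothing; the empty itemset gives 0.
    """
    items = _validate_itemset(itemset, responses.n_items)
    if items.size == 0:
        return 0.0
    sub = params.restrict(items)
    beta_pad, m = _core.pad_beta(sub.beta)
    return _core.loglik(responses.values[:, items], params.theta, beta_pad, sub.alpha, m)


def penalized_objective(responses: ResponseMatrix, itemset, params: GPCMParams,
                        lambda_theta: float, lambda_alpha: float,
                        penalize_theta: bool = True) -> float:
    """F_S = L_S - lambda_theta * sum theta^2 - lambda_alpha * sum (ln alpha)^2.

    The ability penalty is dropped when ``penalize_theta`` is off (used by
    the excluded-set fit, where abilities are fixed, not estimated).
    """
    if lambda_theta < 0 or lambda_alpha < 0:
        raise ValueError("penalty weights must be nonnegative")
    items = _validate_itemset(itemset, responses.n_items)
    f = itemset_loglik(responses, items, params)
    if penalize_theta:
        f -= lambda_theta * float(np.sum(params.theta ** 2))
    if items.size:
        f -= lambda_alpha * float(np.sum(np.log(params.alpha[items]) ** 2))
    return f


def objective_gradient(responses: ResponseMatrix, itemset, params: GPCMParams,
                       lambda_theta: float, lambda_alpha: float,
                       free_blocks=("theta", "beta", "log_alpha"),
                       penalize_theta: bool = True) -> dict:
    """Partial derivatives of the penalized objective.

    Returns a dict with keys drawn from ``free_blocks``: ``theta`` (N,),
    ``beta`` (list of per-item arrays, in itemset order), ``log_alpha``
    (per item in the itemset).  All in the (theta, beta, ln alpha)
    parameterization.
    """
    items = _validate_itemset(itemset, responses.n_items)
    sub = params.restrict(items)
    beta_pad, m = _core.pad_beta(sub.beta)
    want_theta = "theta" in free_blocks
    want_items = "beta" in free_blocks or "log_alpha" in free_blocks
    _, g_theta, g_beta, g_eta = _core.loglik_and_grad(
        responses.values[:, items], params.theta, beta_pad, sub.alpha, m,
        grad_theta=want_theta, grad_items=want_items)
    out = {}
    if want_theta:
        if penalize_theta:
            g_theta = g_theta - 2.0 * lambda_theta * params.theta
        out["theta"] = g_theta
    if "beta" in free_blocks:
        out["beta"] = [g_beta[i, : m[i]] for i in range(len(items))]
    if "log_alpha" in free_blocks:
        out["log_alpha"] = g_eta - 2.0 * lambda_alpha * np.log(sub.alpha)
    return out
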