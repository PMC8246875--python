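"""Penalized joint maximum likelihood fits on included / excluded itemsets.

`fit_included` jointly estimates abilities, thresholds and discriminations
from the included items only; `fit_excluded` freezes those abilities and
refits thresholds and discriminations of the excluded items under a weak
discrimination penalty.  Both are thin wrappers over the
:class:`~ipoqll.estimators.GPCM` estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import GPCMParams, PenaltyConfig, ResponseMatrix
from .estimators import GPCM


@dataclass
class FitResult:
    """Outcome of one penalized JMLE fit, restricted to its itemset."""

    params: GPCMParams
    item_indices: tuple
    item_ids: list
    objective: float
    init_objective: float
    loglik: float
    converged: bool
    n_iterations: int
    gradient_norm: float
    uninformative_subjects: tuple = ()


def _wrap(est: GPCM, items, item_ids) -> FitResult:
    return FitResult(
        params=GPCMParams(est.theta_, est.beta_, est.alpha_) if len(est.beta_) else
        GPCMParams(est.theta_, [], np.empty(0)),
        item_indices=tuple(items),
        item_ids=list(item_ids),
        objective=est.objective_,
        init_objective=est.init_objective_,
        loglik=est.loglik_,
        converged=est.converged_,
        n_iterations=est.n_iter_,
        gradient_norm=est.gradient_norm_,
        uninformative_subjects=est.uninformative_subjects_,
    )


def fit_included(responses: ResponseMatrix, s_in, penalties: PenaltyConfig,
                 init: GPCMParams | None = None, seed: int = 0,
                 n_restarts: int = 1) -> FitResult:
    """Joint fit of (theta, beta, alpha) on the included itemset.

    Maximizes ``L_Sin - lambda_theta * sum theta^2 - lambda_in * sum (ln alpha)^2``.
    Subjects without any observed response on ``s_in`` are reported in the
    result; their ability is determined by the ridge penalty alone (0).
    """
    s_in = sorted(int(i) for i in s_in)
    if not s_in:
        raise ValueError("s_in must be non-empty: abilities cannot be estimated "
                         "without included items")
    sub = responses.subset(s_in)
    est = GPCM(lambda_theta=penalties.lambda_theta, lambda_alpha=penalties.lambda_in,
               n_restarts=n_restarts, random_state=seed)
    est.fit(sub, init=init)
    if not est.converged_:
        warnings.warn(f"included-set fit on {len(s_in)} items did not converge "
                      f"after {est.n_iter_} iterations "
                      f"(gradient norm {est.gradient_norm_:.2e})")
    if est.uninformative_subjects_:
        warnings.warn(f"{len(est.uninformative_subjects_)} subject(s) have no "
                      "observed response on the included itemset; their ability "
                      "is set by the penalty alone")
    return _wrap(est, s_in, sub.item_ids)


def fit_excluded(responses: ResponseMatrix, s_out, theta_fixed,
                 lambda_out: float, init: GPCMParams | None = None) -> FitResult:
    """Fit (beta, alpha) of the excluded items with abilities held fixed.

    Maximizes ``L_Sout(theta_fixed, beta, alpha) - lambda_out * sum (ln alpha)^2``;
    no ability penalty enters (abilities are constants here).  An empty
    excluded set returns an empty fit with objective 0.
    """
    s_out = sorted(int(i) for i in s_out)
    theta_fixed = np.asarray(theta_fixed, dtype=float)
    if theta_fixed.shape[0] != responses.n_subjects:
        raise ValueError("theta_fixed must have one ability per subject")
    if not s_out:
        return FitResult(GPCMParams(theta_fixed, [], np.empty(0)), (), [],
                         0.0, 0.0, 0.0, True, 0, 0.0)
    sub = responses.subset(s_out)
    est = GPCM(lambda_theta=0.0, lambda_alpha=lambda_out, penalize_theta=False,
               fixed_theta=theta_fixed)
    est.fit(sub, init=init)
    if not est.converged_:
        warnings.warn(f"excluded-set fit on {len(s_out)} items did not converge "
                      f"after {est.n_iter_} iterations")
    return _wrap(est, s_out, sub.item_ids)
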