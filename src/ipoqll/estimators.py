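"""scikit-learn style estimators: the GPCM fit and IPOQ-LL item selection.

`GPCM` fits person abilities and item parameters of the generalized
partial credit model by penalized joint maximum likelihood.  `IPOQLLSelector`
is a feature (item) selector driven by the in-plus-out-of-questionnaire
log likelihood; its `transform` keeps the selected instrument's columns.
Both follow the usual sklearn contract (``get_params``/``set_params``,
fitted attributes with a trailing underscore) and compose with pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from . import _core, _fit
from .containers import MISSING, GPCMParams, PenaltyConfig, ResponseMatrix


def as_response_matrix(X, check_coverage=False) -> ResponseMatrix:
    """Coerce an array / DataFrame / ResponseMatrix into a ResponseMatrix.

    NaN cells in float input become missing responses.
    """
    if isinstance(X, ResponseMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ResponseMatrix.from_dataframe(X, check_coverage=check_coverage)
    arr = np.asarray(X)
    if arr.dtype.kind == "f":
        df = pd.DataFrame(arr)
        df.columns = [f"item{i + 1}" for i in range(arr.shape[1])]
        return ResponseMatrix.from_dataframe(df, check_coverage=check_coverage)
    values = arr.astype(np.int64)
    obs = values != MISSING
    n_cat = np.maximum(np.where(obs, values, 0).max(axis=0) + 1, 2)
    rm = ResponseMatrix(values, n_cat)
    if check_coverage:
        rm.check_category_coverage()
    return rm


class GPCM(BaseEstimator):
    """Generalized partial credit model fitted by penalized JMLE.

    Maximizes ``L(theta, beta, alpha) - lambda_theta * sum theta^2
    - lambda_alpha * sum (ln alpha)^2`` over all free parameters with a
    quasi-Newton method (L-BFGS-B) and analytic gradients, in the
    unconstrained (theta, beta, ln alpha) parameterization.

    Parameters
    ----------
    lambda_theta : float, default 0.05
        Ridge weight on the squared abilities.
    lambda_alpha : float, default 50.0
        Ridge weight on the squared log discriminations (the included-set
        default; use a small value such as 0.05 for excluded-set fits).
    penalize_theta : bool, default True
        Include the ability penalty in the objective (ignored when
        ``fixed_theta`` is given, since abilities are then constants).
    fixed_theta : ndarray or None
        When given, abilities are held at these values and only item
        parameters are estimated (the excluded-set fit).
    n_restarts : int, default 1
        Number of optimizer starts; restarts beyond the first jitter the
        initial point (seeded by ``random_state``) and the best final
        objective wins.
    max_iter, gtol, ftol : optimizer controls
        Iteration cap, projected-gradient tolerance and relative
        objective-change tolerance of L-BFGS-B.

    Attributes
    ----------
    theta_, beta_, alpha_, log_alpha_ : fitted parameters
    objective_ : final penalized objective (>= ``init_objective_``)
    loglik_ : unpenalized log likelihood at the fitted parameters
    converged_, n_iter_, gradient_norm_ : optimizer state
    uninformative_subjects_ : indices of subjects with no observed
        response, whose ability is determined by the penalty alone
    """

    def __init__(self, lambda_theta=0.05, lambda_alpha=50.0, penalize_theta=True,
                 fixed_theta=None, n_restarts=1, jitter=0.5, max_iter=500,
                 gtol=1e-5, ftol=1e-9, random_state=0):
        self.lambda_theta = lambda_theta
        self.lambda_alpha = lambda_alpha
        self.penalize_theta = penalize_theta
        self.fixed_theta = fixed_theta
        self.n_restarts = n_restarts
        self.jitter = jitter
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol
        self.random_state = random_state

    def fit(self, X, y=None, init=None):
        """Fit to a subjects x items matrix of category codes.

        ``init`` optionally provides a warm start as a
        :class:`~ipoqll.containers.GPCMParams` (theta ignored when
        abilities are fixed).
        """
        rm = as_response_matrix(X)
        values, m = rm.values, rm.m
        problem = _fit._Problem(values, m, self.lambda_theta, self.lambda_alpha,
                                theta_fixed=self.fixed_theta,
                                penalize_theta=self.penalize_theta)
        if init is not None:
            theta0 = np.asarray(init.theta, float)
            beta_pad0, _ = _core.pad_beta(init.beta, m)
            eta0 = np.log(np.asarray(init.alpha, float))
        else:
            theta0 = _fit.sum_score_theta_init(values, m)
            beta_pad0 = np.zeros((rm.n_items, int(m.max())))
            eta0 = np.zeros(rm.n_items)
        best = None
        rng = np.random.default_rng(self.random_state)
        for start in range(max(1, int(self.n_restarts))):
            if start == 0:
                t0, b0, e0 = theta0, beta_pad0, eta0
            else:
                t0 = theta0 + rng.normal(0, self.jitter, theta0.shape)
                b0 = beta_pad0 + rng.normal(0, self.jitter, beta_pad0.shape)
                e0 = eta0 + rng.normal(0, self.jitter / 2, eta0.shape)
            res = problem.solve(t0, b0, e0, gtol=self.gtol, ftol=self.ftol,
                                max_iter=self.max_iter)
            if best is None or res.objective > best.objective:
                best = res
        self.theta_ = best.theta
        self.beta_ = best.beta
        self.alpha_ = best.alpha
        self.log_alpha_ = np.log(best.alpha) if best.alpha.size else best.alpha
        self.objective_ = best.objective
        self.init_objective_ = best.init_objective
        self.loglik_ = best.loglik
        self.converged_ = best.converged
        self.n_iter_ = best.n_iterations
        self.gradient_norm_ = best.gradient_norm
        self.n_categories_ = rm.n_categories
        self.item_ids_ = list(rm.item_ids)
        self.n_features_in_ = rm.n_items
        self.uninformative_subjects_ = tuple(np.flatnonzero(~rm.observed.any(axis=1)))
        return self

    def params_(self) -> GPCMParams:
        """Fitted parameters as a GPCMParams bundle."""
        return GPCMParams(self.theta_, self.beta_, self.alpha_)

    def predict_proba(self, X=None):
        """Category probabilities (N, P, K_max) at the fitted parameters."""
        beta_pad, m = _core.pad_beta(self.beta_)
        return np.exp(_core.log_category_probs(self.theta_, beta_pad, self.alpha_, m))

    def predict(self, X=None):
        """Model-implied expected response of every subject-item cell."""
        beta_pad, m = _core.pad_beta(self.beta_)
        e, _ = _core.expected_scores_and_variances(self.theta_, beta_pad, self.alpha_, m)
        return e

    def score(self, X, y=None):
        """Unpenalized log likelihood of ``X`` at the fitted parameters."""
        rm = as_response_matrix(X)
        beta_pad, m = _core.pad_beta(self.beta_)
        return _core.loglik(rm.values, self.theta_, beta_pad, self.alpha_, m)


class IPOQLLSelector(SelectorMixin, BaseEstimator):
    """Select a questionnaire's items by maximizing the IPOQ-LL criterion.

    Runs the stepwise (or exhaustive) itemset search and keeps either the
    globally best itemset or, when ``size`` is given, the best itemset of
    that size recorded along the search path.

    Parameters
    ----------
    lambda_theta, lambda_in, lambda_out : penalty weights (see
        :class:`~ipoqll.containers.PenaltyConfig`).
    strategy : {"stepwise", "exhaustive"}
    size : int or None
        Fix the instrument length instead of using the IPOQ-LL maximum.
    min_size : smallest included-set size the search explores.
    n_jobs : candidate evaluations per step run in parallel via joblib.

    Attributes
    ----------
    support_ : boolean mask of the selected items
    trajectory_ : :class:`~ipoqll.search.SearchTrajectory` (stepwise only)
    ipoq_ll_ : criterion value of the selected itemset
    """

    def __init__(self, lambda_theta=0.05, lambda_in=50.0, lambda_out=0.05,
                 strategy="stepwise", size=None, min_size=1, n_jobs=1,
                 random_state=0):
        self.lambda_theta = lambda_theta
        self.lambda_in = lambda_in
        self.lambda_out = lambda_out
        self.strategy = strategy
        self.size = size
        self.min_size = min_size
        self.n_jobs = n_jobs
        self.random_state = random_state

    def fit(self, X, y=None):
        from . import search as _search

        rm = as_response_matrix(X)
        penalties = PenaltyConfig(self.lambda_theta, self.lambda_in, self.lambda_out)
        if self.strategy == "exhaustive":
            itemset, ll = _search.exhaustive_search(rm, penalties, size=self.size,
                                                    n_jobs=self.n_jobs)
            self.trajectory_ = None
        elif self.strategy == "stepwise":
            traj = _search.stepwise_search(rm, penalties, min_size=self.min_size,
                                           seed=self.random_state, n_jobs=self.n_jobs)
            self.trajectory_ = traj
            if self.size is None:
                itemset, ll = traj.optimum
            else:
                itemset = _search.best_subset_of_size(traj, self.size)
                ll = traj.best_by_size[self.size][1]
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.n_features_in_ = rm.n_items
        self.item_ids_ = list(rm.item_ids)
        self.selected_items_ = tuple(sorted(itemset))
        self.ipoq_ll_ = float(ll)
        mask = np.zeros(rm.n_items, dtype=bool)
        mask[list(itemset)] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        return self.support_

    def transform(self, X):
        """Keep only the selected items' columns (missing codes untouched)."""
        if isinstance(X, ResponseMatrix):
            return X.subset(np.flatnonzero(self.support_))
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]
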