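"""Packing and quasi-Newton solving of the penalized JMLE problem.

One `_Problem` instance represents the penalized objective restricted to
one itemset, in the unconstrained (theta, beta, ln alpha) parameterization;
`solve` runs L-BFGS-B on its negative with analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import _core
from .containers import MISSING


@dataclass
class OptResult:
    theta: np.ndarray
    beta: list
    alpha: np.ndarray
    objective: float
    init_objective: float
    loglik: float
    converged: bool
    n_iterations: int
    gradient_norm: float


class _Problem:
    def __init__(self, values, m, lambda_theta, lambda_alpha,
                 theta_fixed=None, penalize_theta=True):
        self.values = values
        self.m = np.asarray(m, dtype=np.int64)
        self.n_subjects, self.n_items = values.shape
        self.lambda_theta = float(lambda_theta)
        self.lambda_alpha = float(lambda_alpha)
        self.theta_fixed = None if theta_fixed is None else np.asarray(theta_fixed, float)
        self.penalize_theta = bool(penalize_theta) and self.theta_fixed is None
        self.free_theta = self.theta_fixed is None
        # beta packing offsets (ragged rows flattened in item order)
        self.beta_offsets = np.concatenate([[0], np.cumsum(self.m)])
        self.n_beta = int(self.beta_offsets[-1])
        self.kernel = _core.Kernel(values, self.m)

    # -- packing -------------------------------------------------------------
    def pack(self, theta, beta_pad, eta):
        parts = []
        if self.free_theta:
            parts.append(np.asarray(theta, float).ravel())
        parts.append(np.concatenate([beta_pad[i, : self.m[i]] for i in range(self.n_items)])
                     if self.n_items else np.empty(0))
        parts.append(np.asarray(eta, float).ravel())
        return np.concatenate(parts)

    def unpack(self, z):
        pos = 0
        if self.free_theta:
            theta = z[: self.n_subjects]
            pos = self.n_subjects
        else:
            theta = self.theta_fixed
        beta_flat = z[pos: pos + self.n_beta]
        beta_pad = np.zeros((self.n_items, int(self.m.max()) if self.n_items else 0))
        for i in range(self.n_items):
            beta_pad[i, : self.m[i]] = beta_flat[self.beta_offsets[i]: self.beta_offsets[i + 1]]
        eta = z[pos + self.n_beta:]
        return theta, beta_pad, eta

    # -- objective -----------------------------------------------------------
    def neg_value_grad(self, z):
        theta, beta_pad, eta = self.unpack(z)
        alpha = np.exp(eta)
        ll, g_theta, g_beta, g_eta = self.kernel.loglik_and_grad(
            theta, beta_pad, alpha, grad_theta=self.free_theta, grad_items=True)
        f = ll - self.lambda_alpha * float(np.sum(eta ** 2))
        g_eta = g_eta - 2.0 * self.lambda_alpha * eta
        parts = []
        if self.free_theta:
            if self.penalize_theta:
                f -= self.lambda_theta * float(np.sum(theta ** 2))
                g_theta = g_theta - 2.0 * self.lambda_theta * theta
            parts.append(g_theta)
        parts.append(np.concatenate([g_beta[i, : self.m[i]] for i in range(self.n_items)])
                     if self.n_items else np.empty(0))
        parts.append(g_eta)
        return -f, -np.concatenate(parts)

    def value(self, z):
        return -self.neg_value_grad(z)[0]

    # -- solving -------------------------------------------------------------
    def solve(self, theta0, beta_pad0, eta0, gtol=1e-5, ftol=1e-9, max_iter=500):
        z0 = self.pack(theta0, beta_pad0, eta0)
        f0 = self.value(z0)
        if z0.size == 0:
            return OptResult(self.theta_fixed if not self.free_theta else theta0,
                             [], np.empty(0), f0, f0, 0.0, True, 0, 0.0)
        res = minimize(self.neg_value_grad, z0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "gtol": gtol, "ftol": ftol})
        theta, beta_pad, eta = self.unpack(res.x)
        alpha = np.exp(eta)
        ll = _core.loglik(self.values, theta, beta_pad, alpha, self.m)
        beta = [beta_pad[i, : self.m[i]].copy() for i in range(self.n_items)]
        return OptResult(theta.copy(), beta, alpha, -float(res.fun), f0, ll,
                         bool(res.status == 0), int(res.nit),
                         float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan)


def sum_score_theta_init(values, m):
    """Standardized, centered raw sum scores; 0 for all-missing subjects."""
    obs = values != MISSING
    x = np.where(obs, values, 0)
    informative = obs.any(axis=1)
    # proportion of the maximum attainable score, robust to missingness
    frac = x.sum(axis=1) / np.maximum((obs * m[None, :]).sum(axis=1), 1)
    theta0 = np.zeros(values.shape[0])
    if informative.any():
        centered = frac[informative] - frac[informative].mean()
        sd = centered.std()
        theta0[informative] = centered / sd if sd > 0 else centered
    return theta0
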