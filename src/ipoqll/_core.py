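"""Vectorized GPCM numerics shared by all fitting code.

Everything here works on padded rectangular arrays: items with fewer
categories than the widest item have their invalid category slots masked
to -inf in the logits.  Responses are (N, P) integer codes with -1 for
missing.  The cumulative logit of category k of item i for subject n is

    s_nik = alpha_i * (k * theta_n - B_ik),   B_ik = sum_{j<=k} beta_ij,

with s_ni0 = 0, and category probabilities are the softmax of s over k.
All gradients are with respect to (theta, beta, log alpha).
"""

from __future__ import annotations

import numpy as np

from .containers import MISSING

try:  # numba accelerates the optimizer's inner loop; numpy path works without
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


def pad_beta(beta_list, m=None):
    """Stack ragged threshold lists into a zero-padded (P, m_max) array."""
    if m is None:
        m = np.array([len(b) for b in beta_list], dtype=np.int64)
    m_max = int(m.max()) if len(m) else 0
    out = np.zeros((len(beta_list), m_max))
    for i, b in enumerate(beta_list):
        out[i, : m[i]] = b
    return out, m


def cumulative_logits(theta, beta_pad, alpha, m):
    """s_nik (N, P, m_max+1) with invalid categories set to -inf."""
    n_cat_max = beta_pad.shape[1] + 1
    k = np.arange(n_cat_max)
    # B_ik = sum of the first k thresholds of item i (B_i0 = 0)
    b_cum = np.concatenate([np.zeros((beta_pad.shape[0], 1)), np.cumsum(beta_pad, axis=1)], axis=1)
    s = alpha[None, :, None] * (k[None, None, :] * theta[:, None, None] - b_cum[None, :, :])
    invalid = k[None, :] > m[:, None]  # (P, K)
    s = np.where(invalid[None, :, :], -np.inf, s)
    return s


def _log_softmax(s):
    """Row-wise log-softmax over the last axis; -inf slots stay -inf.

    Hand-rolled max-subtraction: the k=0 logit is always 0, so the row
    maximum is finite and the shift is safe.
    """
    smax = s.max(axis=-1, keepdims=True)
    es = np.exp(s - smax)
    z = es.sum(axis=-1, keepdims=True)
    return s - smax - np.log(z), es / z


def log_category_probs(theta, beta_pad, alpha, m):
    """Log probabilities (N, P, m_max+1); -inf on invalid categories."""
    s = cumulative_logits(theta, beta_pad, alpha, m)
    return _log_softmax(s)[0]


def loglik(values, theta, beta_pad, alpha, m):
    """Unpenalized log likelihood; missing cells contribute nothing."""
    logp = log_category_probs(theta, beta_pad, alpha, m)
    obs = values != MISSING
    x = np.where(obs, values, 0)
    lp_x = np.take_along_axis(logp, x[:, :, None], axis=2)[:, :, 0]
    return float(np.sum(lp_x[obs]))


def per_item_loglik(values, theta, beta_pad, alpha, m):
    """Log-likelihood contribution of each item (length P)."""
    logp = log_category_probs(theta, beta_pad, alpha, m)
    obs = values != MISSING
    x = np.where(obs, values, 0)
    lp_x = np.take_along_axis(logp, x[:, :, None], axis=2)[:, :, 0]
    return np.where(obs, lp_x, 0.0).sum(axis=0)


@njit(cache=True)
def _cell_loop(values, obs, m, theta, b_cum, alpha, want_theta, want_items):
    """Per-cell log likelihood and gradient accumulation (numba hot loop)."""
    n_sub, n_items = values.shape
    k_max = b_cum.shape[1] - 1
    ll = 0.0
    g_theta = np.zeros(n_sub)
    g_beta = np.zeros((n_items, k_max))
    g_eta = np.zeros(n_items)
    p = np.empty(k_max + 1)
    for n in range(n_sub):
        th = theta[n]
        for i in range(n_items):
            if not obs[n, i]:
                continue
            m_i = m[i]
            a = alpha[i]
            smax = 0.0
            for k in range(m_i + 1):
                s_k = a * (k * th - b_cum[i, k])
                p[k] = s_k
                if s_k > smax:
                    smax = s_k
            z = 0.0
            for k in range(m_i + 1):
                p[k] = np.exp(p[k] - smax)
                z += p[k]
            x = values[n, i]
            ll += a * (x * th - b_cum[i, x]) - smax - np.log(z)
            e_x = 0.0
            e_t = 0.0
            for k in range(m_i + 1):
                p_k = p[k] / z
                p[k] = p_k
                e_x += k * p_k
                e_t += (k * th - b_cum[i, k]) * p_k
            if want_theta:
                g_theta[n] += a * (x - e_x)
            if want_items:
                tail = 0.0
                for j in range(m_i, 0, -1):
                    tail += p[j]
                    ind = 1.0 if x >= j else 0.0
                    g_beta[i, j - 1] -= a * (ind - tail)
                g_eta[i] += a * ((x * th - b_cum[i, x]) - e_t)
    return ll, g_theta, g_beta, g_eta


class Kernel:
    """Likelihood/gradient evaluator with per-dataset constants hoisted.

    Everything that depends only on the responses (observation mask,
    clipped codes, step indicators, invalid-category mask) is built once;
    `loglik_and_grad` then touches only parameter-dependent arrays.  Used
    in the optimizer's inner loop.
    """

    def __init__(self, values, m):
        self.values = values
        self.m = np.asarray(m, dtype=np.int64)
        self.n_items = len(self.m)
        self.m_max = int(self.m.max()) if self.n_items else 0
        self.k = np.arange(self.m_max + 1, dtype=float)
        self.obs = values != MISSING
        self.obs_f = self.obs.astype(float)
        self.obs3_f = self.obs_f[:, :, None]
        self.x = np.where(self.obs, values, 0)
        self.xidx = self.x[:, :, None]
        self.invalid = self.k[None, :] > self.m[:, None]  # (P, K)
        # additive mask: 0 on valid category slots, -inf on invalid ones
        self.neg_mask = np.where(self.invalid, -np.inf, 0.0)
        # 1[x >= j] for thresholds j = 1..m_max, masked by observation
        j = np.arange(1, self.m_max + 1)
        self.ind_obs = (self.xidx >= j[None, None, :]) * self.obs3_f
        self.item_idx = np.arange(self.n_items)[None, :]

    def loglik_and_grad(self, theta, beta_pad, alpha, grad_theta=True,
                        grad_items=True):
        """Returns ``(ll, g_theta, g_beta_pad, g_log_alpha)``.

        Gradient entries for blocks not requested are ``None``;
        ``g_beta_pad`` is padded like ``beta_pad`` with zeros in invalid
        slots.  All with respect to (theta, beta, ln alpha).
        """
        if HAVE_NUMBA:
            b_cum = np.concatenate(
                [np.zeros((self.n_items, 1)), np.cumsum(beta_pad, axis=1)],
                axis=1)
            ll, g_theta, g_beta, g_eta = _cell_loop(
                self.values, self.obs, self.m, np.asarray(theta, float),
                b_cum, np.asarray(alpha, float), grad_theta, grad_items)
            return (ll, g_theta if grad_theta else None,
                    g_beta if grad_items else None,
                    g_eta if grad_items else None)
        b_cum = np.concatenate(
            [np.zeros((self.n_items, 1)), np.cumsum(beta_pad, axis=1)], axis=1)
        t = self.k[None, None, :] * theta[:, None, None] - b_cum[None, :, :]
        s = alpha[None, :, None] * t
        s += self.neg_mask[None, :, :]  # invalid category slots -> -inf
        logp, p = _log_softmax(s)  # invalid slots: logp -inf, p 0

        lp_x = np.take_along_axis(logp, self.xidx, axis=2)[:, :, 0]
        ll = float(np.sum(lp_x * self.obs_f))

        g_theta = g_beta = g_eta = None
        e_score = p @ self.k  # E[X | theta]
        resid = (self.x - e_score) * self.obs_f
        if grad_theta:
            g_theta = resid @ alpha
        if grad_items:
            # d logp_x / d beta_j = -alpha (1[x >= j] - P(X >= j)), j=1..m_i
            tail = np.cumsum(p[:, :, ::-1], axis=2)[:, :, ::-1]  # P(X >= k)
            diff = self.ind_obs - tail[:, :, 1:] * self.obs3_f
            g_beta = -alpha[:, None] * diff.sum(axis=0)
            g_beta[self.invalid[:, 1:]] = 0.0
            # d logp_x / d log alpha = alpha * (t_x - E[t]); p is zero on
            # invalid slots, so the masked product needs no extra mask
            t_x = self.x * theta[:, None] - b_cum[self.item_idx, self.x]
            e_t = np.einsum("npk,npk->np", p, t)
            g_eta = alpha * ((t_x - e_t) * self.obs_f).sum(axis=0)
        return ll, g_theta, g_beta, g_eta


def loglik_and_grad(values, theta, beta_pad, alpha, m,
                    grad_theta=True, grad_items=True):
    """One-shot form of :meth:`Kernel.loglik_and_grad`."""
    return Kernel(values, m).loglik_and_grad(theta, beta_pad, alpha,
                                             grad_theta, grad_items)


def expected_scores_and_variances(theta, beta_pad, alpha, m):
    """Model-implied mean E_ni and variance W_ni of each response."""
    logp = log_category_probs(theta, beta_pad, alpha, m)
    p = np.exp(logp)
    k = np.arange(beta_pad.shape[1] + 1)
    e = np.sum(k[None, None, :] * p, axis=2)
    w = np.sum((k[None, None, :] - e[:, :, None]) ** 2 * p, axis=2)
    return e, w
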