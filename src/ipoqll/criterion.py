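"""The in-plus-out-of-questionnaire log likelihood (IPOQ-LL) of one split.

For a partition of the survey into an included itemset S_in and excluded
itemset S_out, the criterion is computed in five steps: (1) penalized
joint fit on S_in; (2) IQ-LL = unpenalized log likelihood of that fit on
S_in; (3) fit of the excluded items' parameters with abilities frozen;
(4) OQ-LL = unpenalized log likelihood of that fit on S_out;
(5) IPOQ-LL = IQ-LL + OQ-LL.  Every item of the survey contributes to
exactly one of the two terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .containers import GPCMParams, PenaltyConfig, ResponseMatrix
from .estimation import FitResult, fit_excluded, fit_included


@dataclass
class IPOQResult:
    """IQ-LL, OQ-LL and IPOQ-LL of one included/excluded split."""

    s_in: tuple
    s_out: tuple
    iq_ll: float
    oq_ll: float
    ipoq_ll: float
    fit_in: FitResult
    fit_out: FitResult

    def per_item_loglik(self) -> dict:
        """Each item's unpenalized log-likelihood contribution (by index)."""
        out = {}
        for fit in (self.fit_in, self.fit_out):
            if not fit.item_indices:
                continue
            beta_pad, m = _core.pad_beta(fit.params.beta)
            # responses were stored column-subset at fit time; recompute here
            contrib = _core.per_item_loglik(self._values[:, list(fit.item_indices)],
                                            fit.params.theta, beta_pad,
                                            fit.params.alpha, m)
            out.update(dict(zip(fit.item_indices, contrib)))
        return out

    _values: np.ndarray = None  # survey responses, kept for per-item reports


def _warm_init(items, warm: IPOQResult | None, theta, m):
    """Initial parameters for `items`, inheriting a neighboring split's fit."""
    if warm is None:
        return None
    beta, alpha = [], []
    lookup = {}
    for fit in (warm.fit_in, warm.fit_out):
        for pos, idx in enumerate(fit.item_indices):
            lookup[idx] = (fit.params.beta[pos], fit.params.alpha[pos])
    for pos, idx in enumerate(items):
        if idx in lookup and lookup[idx][0].shape[0] == m[pos]:
            beta.append(lookup[idx][0])
            alpha.append(lookup[idx][1])
        else:
            beta.append(np.zeros(m[pos]))
            alpha.append(1.0)
    return GPCMParams(theta, beta, np.asarray(alpha))


def score_split(responses: ResponseMatrix, s_in, penalties: PenaltyConfig,
                warm_start: IPOQResult | None = None, seed: int = 0,
                n_restarts: int = 1) -> IPOQResult:
    """Compute IQ-LL, OQ-LL and IPOQ-LL for the split defined by ``s_in``.

    ``warm_start`` may carry the fits of a neighboring split; shared items
    inherit its parameters as the optimizer's initial point.  Fits always
    run to full tolerance, so warm starts affect speed, not results (up
    to local-optimum effects of the non-convex joint fit).
    """
    s_in = sorted(int(i) for i in s_in)
    if not s_in:
        raise ValueError("s_in must be non-empty")
    all_items = set(range(responses.n_items))
    if not set(s_in) <= all_items:
        raise IndexError("itemset index out of range")
    s_out = sorted(all_items - set(s_in))

    m = responses.m
    theta_init = warm_start.fit_in.params.theta if warm_start is not None else None
    init_in = _warm_init(s_in, warm_start,
                         theta_init if theta_init is not None else np.zeros(responses.n_subjects),
                         m[s_in]) if warm_start is not None else None
    fit_in = fit_included(responses, s_in, penalties, init=init_in, seed=seed,
                          n_restarts=n_restarts)
    iq_ll = fit_in.loglik

    init_out = _warm_init(s_out, warm_start, fit_in.params.theta, m[s_out]) \
        if (warm_start is not None and s_out) else None
    fit_out = fit_excluded(responses, s_out, fit_in.params.theta,
                           penalties.lambda_out, init=init_out)
    oq_ll = fit_out.loglik

    res = IPOQResult(tuple(s_in), tuple(s_out), float(iq_ll), float(oq_ll),
                     float(iq_ll) + float(oq_ll), fit_in, fit_out)
    res._values = responses.values
    return res
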