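"""Standard Rasch diagnostics: fit statistics, residual correlations,
ability standard errors, person separation reliability, random-instrument
baselines and the chance-overlap probability.

Outfit is the unweighted mean of squared standardized residuals of an
item; infit the information-weighted counterpart (Wright-Masters mean
squares).  Values near 1 indicate model-consistent noise; values far
above 1 flag unpredictable items.  Standard errors come from the test
information at the estimated ability, and person separation reliability
is the true-to-observed variance ratio of the ability estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import _core
from .containers import GPCMParams, PenaltyConfig, ResponseMatrix
from .criterion import score_split
from .gpcm_core import category_probabilities


@dataclass
class ItemDiagnostics:
    item_ids: list
    outfit: np.ndarray
    infit: np.ndarray
    alpha_hat: np.ndarray
    residual_corr: np.ndarray
    mean_residual_corr: float        # mean of absolute off-diagonal values
    mean_signed_residual_corr: float
    max_residual_corr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item": self.item_ids, "outfit": self.outfit,
                             "infit": self.infit, "alpha_hat": self.alpha_hat})


@dataclass
class PersonDiagnostics:
    subject_ids: list
    theta_hat: np.ndarray
    se: np.ndarray
    psr: float = np.nan
    rms_se: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject": self.subject_ids,
                             "theta_hat": self.theta_hat, "se": self.se})


def expected_score_and_variance(theta_n: float, beta_i, alpha_i: float):
    """Model-implied mean and variance of one response, E = sum x p_x and
    W = sum (x - E)^2 p_x."""
    p = category_probabilities(theta_n, beta_i, alpha_i)
    k = np.arange(p.shape[0])
    e = float(np.sum(k * p))
    w = float(np.sum((k - e) ** 2 * p))
    return e, w


def _restricted(responses, s_in, params: GPCMParams):
    """Subset matrix and parameters aligned to the itemset."""
    s_in = sorted(int(i) for i in s_in)
    sub = responses.subset(s_in)
    if params.n_items == responses.n_items:
        params = params.restrict(s_in)
    elif params.n_items != len(s_in):
        raise ValueError("params cover neither the full survey nor the itemset")
    return sub, params


def _standardized_residuals(sub, params):
    beta_pad, m = _core.pad_beta(params.beta, sub.m)
    e, w = _core.expected_scores_and_variances(params.theta, beta_pad, params.alpha, m)
    obs = sub.observed
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(obs, (sub.values - e) / np.sqrt(w), np.nan)
    return z, e, w, obs


def fit_statistics(responses: ResponseMatrix, s_in, params: GPCMParams) -> ItemDiagnostics:
    """Outfit / infit mean squares of every included item.

    outfit_i = mean over observed n of z_ni^2, with z = (x - E) / sqrt(W);
    infit_i = sum (x - E)^2 / sum W.  Items answered identically by every
    subject are flagged with a warning (their statistics carry no misfit
    information); statistics that are genuinely undefined (degenerate
    model variance) are reported as NaN.
    """
    sub, params = _restricted(responses, s_in, params)
    z, e, w, obs = _standardized_residuals(sub, params)
    sq = np.where(obs, (sub.values - e) ** 2, 0.0)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        outfit = np.nansum(z ** 2, axis=0) / n_obs
        infit = sq.sum(axis=0) / np.where(obs, w, 0.0).sum(axis=0)
    for j in range(sub.n_items):
        col = sub.values[obs[:, j], j]
        if col.size and np.all(col == col[0]):
            # constant column: the mean squares are still well defined as
            # long as W > 0, but they carry no misfit information
            warnings.warn(f"item {sub.item_ids[j]!r}: zero observed response "
                          "variance, interpret its fit statistics with care")
        if not np.isfinite(outfit[j]):
            warnings.warn(f"item {sub.item_ids[j]!r}: fit statistics undefined "
                          "(degenerate model variance), reported as missing")
            outfit[j] = infit[j] = np.nan
    corr, mean_abs, mean_signed, max_abs = _residual_corr_from_z(z, sub.item_ids)
    return ItemDiagnostics(list(sub.item_ids), outfit, infit, params.alpha.copy(),
                           corr, mean_abs, mean_signed, max_abs)


def _residual_corr_from_z(z, item_ids):
    df = pd.DataFrame(z, columns=item_ids)
    corr = df.corr(min_periods=2).to_numpy()
    off = corr[np.triu_indices_from(corr, k=1)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        return corr, np.nan, np.nan, np.nan
    return corr, float(np.mean(np.abs(off))), float(np.mean(off)), float(np.max(np.abs(off)))


def residual_correlations(responses: ResponseMatrix, s_in, params: GPCMParams):
    """Pairwise Pearson correlations of standardized residuals.

    Returns ``(matrix, mean_abs, max_abs, mean_signed)``; the matrix is
    symmetric with unit diagonal, summaries exclude the diagonal and use
    pairwise-complete observations.  The "no correlation > .3" screening
    flag should be read off ``max_abs``.  Item pairs with a constant
    residual vector are reported as NaN.
    """
    s_in = sorted(int(i) for i in s_in)
    if len(s_in) < 2:
        raise ValueError("residual correlations need at least two items")
    sub, params = _restricted(responses, s_in, params)
    z, *_ = _standardized_residuals(sub, params)
    corr, mean_abs, mean_signed, max_abs = _residual_corr_from_z(z, sub.item_ids)
    if np.isnan(corr[np.triu_indices_from(corr, k=1)]).any():
        warnings.warn("constant residual vector: some item pairs reported as NaN")
    return corr, mean_abs, max_abs, mean_signed


def ability_standard_errors(responses: ResponseMatrix, s_in,
                            params: GPCMParams) -> PersonDiagnostics:
    """Information-based standard errors of the ability estimates.

    se_n = 1 / sqrt(I_n) with test information I_n = sum over observed
    included items of alpha_i^2 W_ni, evaluated at the estimated ability
    (unpenalized information at the penalized estimate).
    """
    sub, params = _restricted(responses, s_in, params)
    beta_pad, m = _core.pad_beta(params.beta, sub.m)
    _, w = _core.expected_scores_and_variances(params.theta, beta_pad, params.alpha, m)
    info = np.where(sub.observed, params.alpha[None, :] ** 2 * w, 0.0).sum(axis=1)
    if np.any(info == 0):
        warnings.warn(f"{int(np.sum(info == 0))} subject(s) carry no information; "
                      "their standard error is undefined")
    with np.errstate(divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(info), np.nan)
    pd_ = PersonDiagnostics(list(sub.subject_ids), params.theta.copy(), se)
    ok = np.isfinite(se)
    pd_.rms_se = float(np.sqrt(np.mean(se[ok] ** 2))) if ok.any() else np.nan
    if ok.sum() >= 2 and np.var(params.theta[ok], ddof=1) > 0:
        pd_.psr = person_separation_reliability(params.theta[ok], se[ok])
    return pd_


def person_separation_reliability(theta_hat, se) -> float:
    """PSR = (observed variance - mean squared SE) / observed variance.

    The true-to-observed variance ratio of the ability estimates, clipped
    to [0, 1]; analogous to Cronbach's alpha.
    """
    theta_hat = np.asarray(theta_hat, float)
    se = np.asarray(se, float)
    if theta_hat.shape != se.shape or theta_hat.size < 2:
        raise ValueError("need >= 2 subjects with defined standard errors")
    var_obs = float(np.var(theta_hat, ddof=1))
    if var_obs == 0:
        raise ValueError("zero observed ability variance: PSR undefined")
    psr = (var_obs - float(np.mean(se ** 2))) / var_obs
    if psr < 0:
        warnings.warn("mean squared SE exceeds the observed variance; "
                      "PSR clipped to 0")
    return float(np.clip(psr, 0.0, 1.0))


def random_instrument_baseline(responses: ResponseMatrix, size: int,
                               n_draws: int, penalties: PenaltyConfig,
                               seed: int = 0, reference=None) -> pd.DataFrame:
    """Reference distributions of instrument statistics for random itemsets.

    Draws ``n_draws`` uniform size-``size`` itemsets (seeded), scores each
    split and computes mean outfit, mean infit, mean absolute residual
    correlation, PSR and IPOQ-LL.  When ``reference`` (an itemset) is
    given, its statistics and their percentiles within the draws are
    attached as ``DataFrame.attrs['reference']`` /
    ``attrs['reference_percentile']``.
    """
    if not (1 <= size < responses.n_items):
        raise ValueError("size must lie in 1..P-1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_draws):
        items = np.sort(rng.choice(responses.n_items, size=size, replace=False))
        rows.append(_instrument_stats(responses, items, penalties))
    out = pd.DataFrame(rows)
    if reference is not None:
        ref = _instrument_stats(responses, sorted(int(i) for i in reference), penalties)
        out.attrs["reference"] = ref
        out.attrs["reference_percentile"] = {
            k: float(np.mean(out[k].to_numpy() <= v) * 100) for k, v in ref.items()}
    return out


def _instrument_stats(responses, items, penalties):
    res = score_split(responses, items, penalties)
    diag = fit_statistics(responses, list(items), res.fit_in.params)
    persons = ability_standard_errors(responses, list(items), res.fit_in.params)
    return {"mean_outfit": float(np.nanmean(diag.outfit)),
            "mean_infit": float(np.nanmean(diag.infit)),
            "mean_abs_residual_corr": diag.mean_residual_corr,
            "psr": persons.psr,
            "ipoq_ll": res.ipoq_ll}


def overlap_tail_probability(pool: int, size_a: int, size_b: int, k: int) -> float:
    """P(|A & B| >= k) for two independent uniform subsets of a pool.

    The overlap of a fixed size-a subset with a uniform size-b subset is
    hypergeometric; the tail sum gives the chance level used to judge the
    agreement of two instruments of the same survey.
    """
    for name, v in (("pool", pool), ("size_a", size_a), ("size_b", size_b), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    if size_a > pool or size_b > pool or k > min(size_a, size_b):
        raise ValueError("infeasible overlap configuration")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, pool, size_a, size_b))
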