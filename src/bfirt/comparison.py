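"""WAIC and PSIS-LOO model comparison from pointwise log-likelihood draws.

The pointwise unit is the person x item cell, with the response-accuracy and
response-time likelihood components scored separately and their indices
adding up to the total (the two components are conditionally independent
given the latent traits).  Everything is reported on the deviance scale
(-2 * elpd), so smaller is better.

PSIS follows the standard Pareto-smoothed importance sampling recipe: the
largest 20% of importance weights (capped at 3*sqrt(S)) are replaced by
expected order statistics of a generalized Pareto distribution fitted to
them by the empirical-Bayes quantile method, then truncated at the raw
maximum.  Observations with a Pareto shape k > 0.7 are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorFit

__all__ = ["waic", "psis_loo", "FitIndices", "fit_indices", "compare",
           "PARETO_K_WARN"]

logger = logging.getLogger(__name__)

PARETO_K_WARN = 0.7


def _validate_pointwise(ll: np.ndarray, min_draws: int = 2) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be draws x observations")
    if ll.shape[0] < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {ll.shape[0]}")
    if not np.isfinite(ll).all():
        raise ValueError("non-finite pointwise log-likelihood values")
    return ll


def waic(pointwise: np.ndarray) -> Tuple[float, float, float]:
    """Widely applicable information criterion.

    Returns ``(waic, lppd, p_waic)`` with
    ``lppd = sum_i log mean_s exp(ll_is)``,
    ``p_waic = sum_i var_s(ll_is)`` and ``waic = -2 (lppd - p_waic)``.
    """
    ll = _validate_pointwise(pointwise)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), lppd, p_waic


# ---------------------------------------------------------------------------
# Pareto smoothed importance sampling
# ---------------------------------------------------------------------------

def _gpd_fit(x: np.ndarray) -> Tuple[float, float]:
    """Empirical-Bayes generalized-Pareto fit to sorted exceedances."""
    prior_bs, prior_k = 3.0, 10.0
    n = len(x)
    m_est = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m_est / (np.arange(1, m_est + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x[None, :]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        profile = n * (np.log(-(b / k)) - k - 1.0)
    w = 1.0 / np.exp(profile - profile[:, None]).sum(axis=1)
    keep = w >= 10 * np.finfo(float).eps
    w, b = w[keep], b[keep]
    w /= w.sum()
    b_post = float(np.sum(b * w))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.full_like(p, np.nan)
    if abs(k) < np.finfo(float).eps:
        return sigma * (-np.log1p(-p))
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def smooth_log_weights(log_weights: np.ndarray) -> Tuple[np.ndarray, float]:
    """Pareto-smooth one observation's importance log-weights.

    Returns the self-normalized smoothed log weights and the fitted Pareto
    shape ``k`` (inf when the tail was too short to fit).
    """
    x = np.array(log_weights, dtype=float)
    S = len(x)
    x -= x.max()
    if np.ptp(x) < 1e-12:
        # constant weights: nothing to smooth, no tail index
        return x - logsumexp(x), -np.inf
    n_tail = int(np.ceil(min(0.2 * S, 3.0 * np.sqrt(S))))
    order = np.argsort(x)
    cutoff = max(x[order[-n_tail - 1]], np.log(np.finfo(float).tiny))
    tail_ids = np.flatnonzero(x > cutoff)
    khat = np.inf
    if len(tail_ids) > 4:
        tail = x[tail_ids]
        tail_order = np.argsort(tail)
        exc = np.exp(tail) - np.exp(cutoff)
        khat, sigma = _gpd_fit(exc[tail_order])
        if np.isfinite(khat):
            p = (np.arange(0.5, len(tail)) / len(tail))
            smoothed = np.log(_gpd_quantile(p, khat, sigma) + np.exp(cutoff))
            x[tail_ids[tail_order]] = smoothed
            x[x > 0] = 0.0
    return x - logsumexp(x), float(khat)


def psis_loo(pointwise: np.ndarray) -> Tuple[float, float, np.ndarray]:
    """PSIS leave-one-out cross-validation on the deviance scale.

    Returns ``(loo, p_loo, pareto_k)``.  Importance weights for leaving out
    observation *i* are ``1/p(y_i | draw)``; their upper tail is Pareto
    smoothed per observation.  A warning is emitted when any shape estimate
    exceeds 0.7 (unreliable importance sampling for that cell).
    """
    ll = _validate_pointwise(pointwise, min_draws=2)
    S, n_obs = ll.shape
    if S < 100:
        logger.info("PSIS-LOO with only %d draws; Pareto fits may be unstable", S)
    elpd = np.empty(n_obs)
    ks = np.empty(n_obs)
    for i in range(n_obs):
        lw, k = smooth_log_weights(-ll[:, i])
        elpd[i] = logsumexp(lw + ll[:, i])
        ks[i] = k
    n_bad = int(np.sum(ks > PARETO_K_WARN))
    if n_bad:
        warnings.warn(
            f"{n_bad} observation(s) with Pareto k > {PARETO_K_WARN}; "
            "PSIS-LOO may be unreliable for them", RuntimeWarning)
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    elpd_loo = float(elpd.sum())
    return -2.0 * elpd_loo, lppd - elpd_loo, ks


@dataclass(frozen=True)
class FitIndices:
    """Table-ready WAIC/LOO indices for one fitted model."""

    model: str
    waic_ra: float
    waic_rt: float
    waic_total: float
    loo_ra: float
    loo_rt: float
    loo_total: float
    lppd_ra: float
    lppd_rt: float
    p_waic_ra: float
    p_waic_rt: float
    p_loo_ra: float
    p_loo_rt: float
    pareto_k_max: float
    n_pareto_k_warn: int


def fit_indices(fit: PosteriorFit, label: Optional[str] = None) -> FitIndices:
    """Compute WAIC and PSIS-LOO for the RA and RT components of one fit.

    Component indices are computed on each component's own cells; totals are
    their sums (equivalently, the indices of the concatenated cells).
    """
    label = label or fit.spec.variant.value
    ll_ra = fit.pointwise_loglik("ra").astype(np.float64)
    ll_rt = fit.pointwise_loglik("rt").astype(np.float64)
    return indices_from_pointwise(label, ll_ra, ll_rt)


def indices_from_pointwise(label: str, ll_ra: np.ndarray,
                           ll_rt: np.ndarray) -> FitIndices:
    """WAIC/LOO indices from raw draws x cells matrices (RA and RT)."""
    w_ra, lppd_ra, p_ra = waic(ll_ra)
    w_rt, lppd_rt, p_rt = waic(ll_rt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        l_ra, pl_ra, k_ra = psis_loo(ll_ra)
        l_rt, pl_rt, k_rt = psis_loo(ll_rt)
    ks = np.concatenate([k_ra, k_rt])
    finite_ks = ks[np.isfinite(ks)]
    return FitIndices(
        model=label,
        waic_ra=w_ra, waic_rt=w_rt, waic_total=w_ra + w_rt,
        loo_ra=l_ra, loo_rt=l_rt, loo_total=l_ra + l_rt,
        lppd_ra=lppd_ra, lppd_rt=lppd_rt,
        p_waic_ra=p_ra, p_waic_rt=p_rt,
        p_loo_ra=pl_ra, p_loo_rt=pl_rt,
        pareto_k_max=float(finite_ks.max()) if len(finite_ks) else np.nan,
        n_pareto_k_warn=int(np.sum(ks > PARETO_K_WARN)),
    )


def compare(fits: Sequence[PosteriorFit],
            labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Rank candidate models fitted to the same data by total WAIC.

    All fits must score identical observation sets; mismatched data shapes
    or missingness patterns are rejected as incomparable.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if f.structure.N != ref.structure.N or f.structure.m != ref.structure.m:
            raise ValueError("fits have different data dimensions; incomparable")
        if not np.array_equal(f.posterior._u, ref.posterior._u) or \
           not np.array_equal(f.posterior._obs_rt, ref.posterior._obs_rt):
            raise ValueError("fits were made on different data; incomparable")
    if labels is None:
        labels = [f.spec.variant.value for f in fits]
    rows = [fit_indices(f, lab) for f, lab in zip(fits, labels)]
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("waic_total", kind="stable").reset_index(drop=True)
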