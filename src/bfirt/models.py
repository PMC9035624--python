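"""Level-1 likelihoods and level-2 population structure of the joint
hierarchical model family.

The family couples a bi-factor two-parameter logistic IRT model for response
accuracy (RA) with a bi-factor lognormal model for response time (RT).  Every
item loads on one general factor (ability ``theta_g`` on the RA side, speed
``tau_g`` on the RT side) and on exactly one specific factor determined by a
between-item loading pattern.  Constraint cases of the same family:

* ``BFHM``   — general + specific factors on both sides (the full model).
* ``CMHM``   — no general factors (``a_g = alpha_g = 0``).
* ``PMHM``   — CMHM with a single (unidimensional) speed factor.
* ``UNIDIM`` — a single factor on both sides.

All functions here are pure and deterministic; sampling lives in
:mod:`bfirt.simulate` and :mod:`bfirt.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "LoadingPattern",
    "ModelVariant",
    "ModelSpec",
    "ItemParameters",
    "PersonParameters",
    "PopulationStructure",
    "PointwiseLoglik",
    "irt_prob",
    "log_rt_mean",
    "log_rt_logdensity",
    "pointwise_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LoadingPattern:
    """Between-item loading pattern: each item measures one specific dimension.

    Equivalent to a 0/1 indicator matrix ``S`` of shape
    ``(n_items, n_specific)`` in which every row has exactly one 1 (each item
    loads on a single specific factor) and every column has at least one 1
    (no empty dimension).

    Parameters
    ----------
    n_items, n_specific
        Test length and number of specific dimensions.
    group_of
        Integer array of length ``n_items`` mapping each item to its specific
        dimension, coded ``0 .. n_specific - 1``.
    """

    n_items: int
    n_specific: int
    group_of: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.group_of, dtype=np.int64)
        object.__setattr__(self, "group_of", g)
        if self.n_items <= 0 or self.n_specific <= 0:
            raise ValueError("n_items and n_specific must be positive")
        if g.shape != (self.n_items,):
            raise ValueError(
                f"group_of has shape {g.shape}, expected ({self.n_items},)"
            )
        if g.min() < 0 or g.max() >= self.n_specific:
            raise ValueError("group indices must lie in [0, n_specific)")
        counts = np.bincount(g, minlength=self.n_specific)
        if (counts == 0).any():
            empty = np.flatnonzero(counts == 0).tolist()
            raise ValueError(f"specific dimension(s) {empty} have no items")

    @classmethod
    def from_blocks(cls, group_sizes: "list[int] | tuple[int, ...]") -> "LoadingPattern":
        """Contiguous blocks of items per dimension, e.g. ``[10, 10, 10]``."""
        sizes = [int(s) for s in group_sizes]
        if any(s <= 0 for s in sizes):
            raise ValueError("all group sizes must be positive")
        group_of = np.repeat(np.arange(len(sizes)), sizes)
        return cls(n_items=int(sum(sizes)), n_specific=len(sizes), group_of=group_of)

    def indicator_matrix(self) -> np.ndarray:
        """The 0/1 matrix ``S`` (items x specific dimensions)."""
        S = np.zeros((self.n_items, self.n_specific), dtype=np.int64)
        S[np.arange(self.n_items), self.group_of] = 1
        return S


class ModelVariant(str, Enum):
    BFHM = "bfhm"
    CMHM = "cmhm"
    PMHM = "pmhm"
    UNIDIM = "unidim"


@dataclass(frozen=True)
class ModelSpec:
    """Which constraint case of the family to use.

    ``has_general`` is true only for the full bi-factor model.  The RA side
    keeps the pattern's specific dimensions except under ``UNIDIM``; the RT
    side collapses to a single speed dimension under ``PMHM`` and ``UNIDIM``.
    """

    variant: ModelVariant = ModelVariant.BFHM

    @property
    def has_general(self) -> bool:
        return self.variant is ModelVariant.BFHM

    def n_ability_specific(self, pattern: LoadingPattern) -> int:
        return 1 if self.variant is ModelVariant.UNIDIM else pattern.n_specific

    def n_speed_specific(self, pattern: LoadingPattern) -> int:
        if self.variant in (ModelVariant.PMHM, ModelVariant.UNIDIM):
            return 1
        return pattern.n_specific

    def ability_group_of(self, pattern: LoadingPattern) -> np.ndarray:
        if self.variant is ModelVariant.UNIDIM:
            return np.zeros(pattern.n_items, dtype=np.int64)
        return pattern.group_of

    def speed_group_of(self, pattern: LoadingPattern) -> np.ndarray:
        if self.variant in (ModelVariant.PMHM, ModelVariant.UNIDIM):
            return np.zeros(pattern.n_items, dtype=np.int64)
        return pattern.group_of


def _positive(name: str, x: np.ndarray) -> None:
    if (x <= 0).any():
        raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ItemParameters:
    """Item-side parameters of both level-1 models.

    ``a_g``/``a_s`` are the general/specific RA discriminations, ``d`` the RA
    location (easiness), ``alpha_g``/``alpha_s`` the general/specific speed
    slopes, ``beta`` the time intensity (expected log-seconds at zero speed)
    and ``sigma`` the residual SD of log time; ``1/sigma`` plays the role of a
    time-discrimination parameter.
    """

    a_g: np.ndarray
    a_s: np.ndarray
    d: np.ndarray
    alpha_g: np.ndarray
    alpha_s: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("a_g", "a_s", "d", "alpha_g", "alpha_s", "beta", "sigma"):
            arrays[name] = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, arrays[name])
        m = arrays["d"].shape[0]
        for name, arr in arrays.items():
            if arr.shape != (m,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({m},)")
        # a_g/alpha_g may be exactly zero (reduced models); never negative.
        for name in ("a_g", "alpha_g"):
            if (arrays[name] < 0).any():
                raise ValueError(f"{name} must be non-negative")
        for name in ("a_s", "alpha_s", "sigma"):
            _positive(name, arrays[name])

    @property
    def n_items(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class PersonParameters:
    """Latent abilities and speeds: general vectors plus person x specific
    dimension matrices."""

    theta_g: np.ndarray
    theta_s: np.ndarray
    tau_g: np.ndarray
    tau_s: np.ndarray

    def __post_init__(self) -> None:
        tg = np.atleast_1d(np.asarray(self.theta_g, dtype=float))
        ug = np.atleast_1d(np.asarray(self.tau_g, dtype=float))
        ts = np.atleast_2d(np.asarray(self.theta_s, dtype=float))
        us = np.atleast_2d(np.asarray(self.tau_s, dtype=float))
        n = tg.shape[0]
        if ug.shape != (n,):
            raise ValueError("theta_g and tau_g must have equal length")
        if ts.shape[0] != n or us.shape[0] != n:
            raise ValueError("specific matrices must have one row per person")
        for name, arr in (("theta_g", tg), ("theta_s", ts), ("tau_g", ug), ("tau_s", us)):
            object.__setattr__(self, name, arr)

    @property
    def n_persons(self) -> int:
        return self.theta_g.shape[0]


@dataclass(frozen=True)
class PopulationStructure:
    """Level-2 moments linking abilities to speeds and ``d`` to ``beta``.

    Person factors are identified to mean 0 / variance 1, so each 2x2 person
    covariance is a correlation matrix and ``rho_theta_g_tau_g`` (and the
    per-dimension ``rho_theta_s_tau_s``) fully describe it.  The item pair
    ``(d, beta)`` keeps free means and scales.
    """

    rho_theta_g_tau_g: float
    rho_theta_s_tau_s: np.ndarray
    mu_d: float
    mu_beta: float
    sigma_d: float
    sigma_beta: float
    rho_d_beta: float

    def __post_init__(self) -> None:
        rs = np.atleast_1d(np.asarray(self.rho_theta_s_tau_s, dtype=float))
        object.__setattr__(self, "rho_theta_s_tau_s", rs)
        for name in ("rho_theta_g_tau_g", "rho_d_beta"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if (np.abs(rs) > 1).any():
            raise ValueError("specific correlations must lie in [-1, 1]")
        if self.sigma_d <= 0 or self.sigma_beta <= 0:
            raise ValueError("sigma_d and sigma_beta must be positive")

    @property
    def sigma_d_beta(self) -> float:
        """Covariance of (d, beta)."""
        return self.rho_d_beta * self.sigma_d * self.sigma_beta


# ---------------------------------------------------------------------------
# Level-1 likelihood pieces
# ---------------------------------------------------------------------------

def irt_prob(d, a_g, a_s, theta_g, theta_s):
    """Probability of a correct response under the bi-factor 2PL.

    ``P = logistic(d + a_g * theta_g + a_s * theta_s)``; broadcasts over any
    conforming shapes and is stable for linear predictors out to +-700.
    """
    eta = np.asarray(d, dtype=float) + np.asarray(a_g, dtype=float) * theta_g \
        + np.asarray(a_s, dtype=float) * theta_s
    return expit(eta)


def log_rt_mean(beta, alpha_g, alpha_s, tau_g, tau_s):
    """Mean of log response time: ``beta - (alpha_g*tau_g + alpha_s*tau_s)``."""
    return np.asarray(beta, dtype=float) - (
        np.asarray(alpha_g, dtype=float) * tau_g
        + np.asarray(alpha_s, dtype=float) * tau_s
    )


def log_rt_logdensity(t, beta, alpha_g, alpha_s, sigma, tau_g, tau_s):
    """Log density of the observed time on the log-time scale.

    The model states ``ln T ~ Normal(beta - alpha_g*tau_g - alpha_s*tau_s,
    sigma^2)``; this returns the normal log density evaluated at ``ln t``
    (no change-of-variables Jacobian to the seconds scale, so absolute fit
    indices are on the log-time scale for every variant alike).
    """
    t = np.asarray(t, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (t <= 0).any():
        raise ValueError("response times must be strictly positive")
    if (sigma <= 0).any():
        raise ValueError("sigma must be strictly positive")
    z = (np.log(t) - log_rt_mean(beta, alpha_g, alpha_s, tau_g, tau_s)) / sigma
    return -0.5 * (_LOG_2PI + z * z) - np.log(sigma)


class PointwiseLoglik(NamedTuple):
    """Cell-level log likelihoods with missingness bookkeeping."""

    ra: np.ndarray
    rt: np.ndarray
    n_missing_ra: int
    n_missing_rt: int

    @property
    def total(self) -> float:
        return float(self.ra.sum() + self.rt.sum())


def _effective_loadings(items: ItemParameters, spec: ModelSpec):
    """General loadings after applying the variant constraints."""
    if spec.has_general:
        return items.a_g, items.alpha_g
    z = np.zeros_like(items.a_g)
    return z, z


def pointwise_loglik(
    U: np.ndarray,
    T: np.ndarray,
    items: ItemParameters,
    persons: PersonParameters,
    pattern: LoadingPattern,
    spec: ModelSpec = ModelSpec(),
) -> PointwiseLoglik:
    """Person x item log-likelihood matrices for the RA and RT components.

    Missing cells (NaN) contribute exactly 0 and are counted.  Under reduced
    variants the general loadings are forced to zero and the specific factor
    selection follows the variant's collapsed pattern, which makes the
    reduction chain exact: a BFHM evaluation with ``a_g = alpha_g = 0``
    equals the CMHM evaluation bit for bit.
    """
    U = np.asarray(U, dtype=float)
    T = np.asarray(T, dtype=float)
    N, m = U.shape
    if T.shape != (N, m):
        raise ValueError(f"U has shape {U.shape} but T has shape {T.shape}")
    if m != pattern.n_items or m != items.n_items or N != persons.n_persons:
        raise ValueError("data, pattern and parameter shapes disagree")

    obs_ra = ~np.isnan(U)
    obs_rt = ~np.isnan(T)
    vals = U[obs_ra]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("responses must be 0, 1 or missing")
    if (T[obs_rt] <= 0).any():
        raise ValueError("response times must be strictly positive")

    a_g, alpha_g = _effective_loadings(items, spec)
    g_ra = spec.ability_group_of(pattern)
    g_rt = spec.speed_group_of(pattern)
    theta_s = persons.theta_s[:, g_ra]           # N x m gather
    tau_s = persons.tau_s[:, g_rt]

    eta = items.d[None, :] + a_g[None, :] * persons.theta_g[:, None] \
        + items.a_s[None, :] * theta_s
    # log Bernoulli via log-sigmoid: u*log p + (1-u)*log(1-p)
    Usafe = np.where(obs_ra, U, 0.0)
    ll_ra = np.where(obs_ra, log_expit(np.where(Usafe == 1.0, eta, -eta)), 0.0)

    mu = items.beta[None, :] - (
        alpha_g[None, :] * persons.tau_g[:, None] + items.alpha_s[None, :] * tau_s
    )
    Tsafe = np.where(obs_rt, T, 1.0)
    z = (np.log(Tsafe) - mu) / items.sigma[None, :]
    ll_rt = np.where(
        obs_rt,
        -0.5 * (_LOG_2PI + z * z) - np.log(items.sigma[None, :]),
        0.0,
    )
    return PointwiseLoglik(
        ra=ll_ra,
        rt=ll_rt,
        n_missing_ra=int(N * m - obs_ra.sum()),
        n_missing_rt=int(N * m - obs_rt.sum()),
    )
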