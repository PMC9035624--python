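"""Synthetic joint RA+RT data under the full bi-factor generating process.

The generator mirrors the model's own hierarchy: item loadings and the
RT residual SD ``sigma`` are half-normal (standard normal truncated to the
positive axis), ``(d, beta)`` is bivariate normal with means ``(0, 4)``, variances
``(1, 0.25)`` and covariance ``-0.25``; each ability--speed factor pair is
bivariate standard normal with a correlation drawn fresh from Uniform(-1, 1),
and factor pairs are mutually independent (bi-factor orthogonality).
Accuracies are Bernoulli through the logistic response function and log times
are normal around the speed-adjusted time intensity.

Randomness is split into independent substreams (items, correlations,
persons, RA noise, RT noise) of one master seed, so e.g. changing the number
of examinees never perturbs the item parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .models import (
    ItemParameters,
    LoadingPattern,
    PersonParameters,
    PopulationStructure,
    irt_prob,
    log_rt_mean,
)

__all__ = ["SimConfig", "TruthBundle", "generate_item_params",
           "generate_person_params", "simulate_dataset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the simulation design of the model family: 3 specific
    dimensions with equal item groups, half-normal loadings, and the stated
    (d, beta) moments.  ``group_sizes=None`` splits ``m`` equally (requires
    divisibility).
    """

    N: int = 500
    m: int = 30
    n_specific: int = 3
    group_sizes: Optional[tuple] = None
    seed: int = 0
    mu_d: float = 0.0
    mu_beta: float = 4.0
    var_d: float = 1.0
    var_beta: float = 0.25
    cov_d_beta: float = -0.25
    # when set, overrides the Uniform(-1,1) draw for the stated factor pair
    rho_general: Optional[float] = None
    rho_specific: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.N <= 0 or self.m <= 0 or self.n_specific <= 0:
            raise ValueError("N, m and n_specific must be positive")
        if self.group_sizes is not None:
            gs = tuple(int(g) for g in self.group_sizes)
            object.__setattr__(self, "group_sizes", gs)
            if len(gs) != self.n_specific or sum(gs) != self.m:
                raise ValueError("group_sizes must partition m into n_specific groups")
        elif self.m % self.n_specific:
            raise ValueError("m must be divisible by n_specific for equal groups")
        cov = np.array([[self.var_d, self.cov_d_beta],
                        [self.cov_d_beta, self.var_beta]])
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("(d, beta) covariance matrix must be positive definite")

    @property
    def pattern(self) -> LoadingPattern:
        sizes = self.group_sizes or (self.m // self.n_specific,) * self.n_specific
        return LoadingPattern.from_blocks(list(sizes))

    def item_cov(self) -> np.ndarray:
        return np.array([[self.var_d, self.cov_d_beta],
                         [self.cov_d_beta, self.var_beta]])


@dataclass(frozen=True)
class TruthBundle:
    """Everything the generator actually used, for recovery bookkeeping."""

    config: SimConfig
    items: ItemParameters
    persons: PersonParameters
    structure: PopulationStructure

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        return {
            "config": cfg,
            "items": {k: getattr(self.items, k).tolist()
                      for k in ("a_g", "a_s", "d", "alpha_g", "alpha_s", "beta", "sigma")},
            "persons": {k: getattr(self.persons, k).tolist()
                        for k in ("theta_g", "theta_s", "tau_g", "tau_s")},
            "structure": {
                "rho_theta_g_tau_g": self.structure.rho_theta_g_tau_g,
                "rho_theta_s_tau_s": self.structure.rho_theta_s_tau_s.tolist(),
                "mu_d": self.structure.mu_d,
                "mu_beta": self.structure.mu_beta,
                "sigma_d": self.structure.sigma_d,
                "sigma_beta": self.structure.sigma_beta,
                "rho_d_beta": self.structure.rho_d_beta,
            },
        }


def _substreams(seed: int):
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(5)
    return {name: np.random.default_rng(kid)
            for name, kid in zip(("items", "corr", "persons", "ra", "rt"), kids)}


def _half_normal(rng: np.random.Generator, size: int) -> np.ndarray:
    # standard normal truncated to (0, inf) == half-normal
    return np.abs(rng.standard_normal(size))


def generate_item_params(config: SimConfig,
                         rng: Optional[np.random.Generator] = None) -> ItemParameters:
    """Draw all item parameters for one replication.

    Loadings ``a_g, a_s, alpha_g, alpha_s`` and the residual SD ``sigma``
    are half-normal (keeping the residual scale bounded, so no item's time
    intensity is effectively unidentifiable); ``(d, beta)`` is jointly
    bivariate normal with the configured moments.
    """
    if rng is None:
        rng = _substreams(config.seed)["items"]
    m = config.m
    a_g = _half_normal(rng, m)
    a_s = _half_normal(rng, m)
    alpha_g = _half_normal(rng, m)
    alpha_s = _half_normal(rng, m)
    sigma = _half_normal(rng, m)                 # RT residual SD
    L = np.linalg.cholesky(config.item_cov())
    db = np.array([config.mu_d, config.mu_beta])[None, :] \
        + rng.standard_normal((m, 2)) @ L.T
    return ItemParameters(a_g=a_g, a_s=a_s, d=db[:, 0], alpha_g=alpha_g,
                          alpha_s=alpha_s, beta=db[:, 1], sigma=sigma)


def generate_person_params(config: SimConfig,
                           rng_corr: Optional[np.random.Generator] = None,
                           rng_person: Optional[np.random.Generator] = None):
    """Draw factor correlations and the person traits.

    For the general pair and each specific pair the ability--speed
    correlation is Uniform(-1, 1) (unless pinned in the config), then the
    N pairs are bivariate standard normal with that correlation; pairs are
    independent across factors.
    """
    if rng_corr is None or rng_person is None:
        streams = _substreams(config.seed)
        rng_corr = rng_corr or streams["corr"]
        rng_person = rng_person or streams["persons"]
    S = config.n_specific
    rho_g = (config.rho_general if config.rho_general is not None
             else float(rng_corr.uniform(-1, 1)))
    if config.rho_specific is not None:
        rho_s = np.asarray(config.rho_specific, dtype=float)
        if rho_s.shape != (S,):
            raise ValueError("rho_specific must give one correlation per dimension")
    else:
        rho_s = rng_corr.uniform(-1, 1, size=S)
    for r in np.concatenate(([rho_g], rho_s)):
        if abs(r) > 0.99:
            warnings.warn(
                f"near-singular factor correlation {r:.4f} drawn; the pair's "
                "covariance matrix is almost rank deficient", RuntimeWarning)

    def bvn_pair(rho: float, n: int) -> np.ndarray:
        z = rng_person.standard_normal((n, 2))
        out = np.empty_like(z)
        out[:, 0] = z[:, 0]
        out[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
        return out

    gen = bvn_pair(rho_g, config.N)
    theta_s = np.empty((config.N, S))
    tau_s = np.empty((config.N, S))
    for s in range(S):
        pair = bvn_pair(float(rho_s[s]), config.N)
        theta_s[:, s] = pair[:, 0]
        tau_s[:, s] = pair[:, 1]
    persons = PersonParameters(theta_g=gen[:, 0], theta_s=theta_s,
                               tau_g=gen[:, 1], tau_s=tau_s)
    structure = PopulationStructure(
        rho_theta_g_tau_g=rho_g,
        rho_theta_s_tau_s=rho_s,
        mu_d=config.mu_d,
        mu_beta=config.mu_beta,
        sigma_d=float(np.sqrt(config.var_d)),
        sigma_beta=float(np.sqrt(config.var_beta)),
        rho_d_beta=float(config.cov_d_beta
                         / np.sqrt(config.var_d * config.var_beta)),
    )
    return persons, structure


def simulate_dataset(config: SimConfig):
    """Simulate one joint dataset.

    Returns ``(U, T, truth)`` where ``U`` is the N x m 0/1 accuracy matrix,
    ``T`` the N x m response-time matrix in seconds, and ``truth`` the
    :class:`TruthBundle`.  A response is scored correct when the model
    probability is >= a fresh Uniform(0, 1) draw; log times are normal with
    the model mean and item residual SD.
    """
    streams = _substreams(config.seed)
    items = generate_item_params(config, streams["items"])
    persons, structure = generate_person_params(config, streams["corr"],
                                                streams["persons"])
    pattern = config.pattern
    g = pattern.group_of

    P = irt_prob(items.d[None, :], items.a_g[None, :], items.a_s[None, :],
                 persons.theta_g[:, None], persons.theta_s[:, g])
    U = (P >= streams["ra"].uniform(size=P.shape)).astype(np.int8)

    mu = log_rt_mean(items.beta[None, :], items.alpha_g[None, :],
                     items.alpha_s[None, :], persons.tau_g[:, None],
                     persons.tau_s[:, g])
    lnT = mu + items.sigma[None, :] * streams["rt"].standard_normal(mu.shape)
    T = np.exp(lnT)
    truth = TruthBundle(config=config, items=items, persons=persons,
                        structure=structure)
    return U, T, truth
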