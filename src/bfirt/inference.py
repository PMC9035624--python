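"""Bayesian estimation of the hierarchical model family by NUTS.

Estimation follows the model's stated protocol: half-normal priors on all
loadings and on the time discrimination ``1/sigma``, LKJ(eta=1) (uniform)
priors on the 2x2 ability--speed and (d, beta) correlations, normal
hyper-priors ``mu_d ~ N(0, 0.5)`` and ``mu_beta ~ N(4, 0.5)``, half-normal
priors on ``sigma_d, sigma_beta``.  Identification fixes every person factor
to mean 0 and variance 1, and the strictly positive loadings pin the factor
signs, so no post-hoc reflection is needed.

Point estimates are posterior means (EAP).  Convergence is judged by the
split-chain potential scale reduction factor (PSRF), flagged against a
threshold of 1.1.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ._posterior import JointPosterior, ModelStructure, ParamLayout
from .models import LoadingPattern, ModelSpec
from .nuts import NutsResult, sample_nuts

__all__ = ["PriorConfig", "SamplerConfig", "PosteriorFit", "fit",
           "compute_psrf", "extract_structure"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorConfig:
    """Hyper-parameters of the prior.

    ``eta`` is the LKJ shape for every 2x2 correlation block (1 = uniform
    over the correlation).  The loading / time-discrimination prior is the
    standard normal truncated to (0, inf) and is part of the model itself.
    """

    eta: float = 1.0
    mu_d_loc: float = 0.0
    mu_d_scale: float = 0.5
    mu_beta_loc: float = 4.0
    mu_beta_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.mu_d_scale <= 0 or self.mu_beta_scale <= 0:
            raise ValueError("hyper-prior scales must be positive")
        if self.mu_d_scale != self.mu_beta_scale:
            raise ValueError(
                "a single scale is used for both mean hyper-priors")


@dataclass(frozen=True)
class SamplerConfig:
    """Chain layout.

    ``iterations`` counts MCMC iterations summed over chains, warmup
    included, mirroring a "total iterations" budget; each chain runs
    ``iterations // chains`` iterations of which ``warmup_fraction`` are
    adaptation, and every ``thin``-th post-warmup draw is retained.  The
    default (2 chains x 20,000; half warmup; thinning 2) keeps the final
    20,000 pre-thinning iterations, i.e. 10,000 retained draws.
    """

    chains: int = 2
    iterations: int = 40_000
    thin: int = 2
    warmup_fraction: float = 0.5
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    psrf_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for PSRF")
        if self.thin < 1 or self.iterations < self.chains * 4:
            raise ValueError("invalid iteration/thinning settings")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")

    @property
    def per_chain(self) -> int:
        return self.iterations // self.chains

    @property
    def warmup(self) -> int:
        return int(self.per_chain * self.warmup_fraction)

    @property
    def draws_per_chain(self) -> int:
        return self.per_chain - self.warmup


def compute_psrf(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``draws`` has shape (chains, iterations).  Each chain is split in half
    (detecting within-chain drift); the statistic is
    ``sqrt(((n-1)/n * W + B/n) / W)``.  Constant chains return 1 by
    convention (the 0/0 case) with a warning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws from at least 2 chains")
    if draws.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    n_half = draws.shape[1] // 2
    halves = np.concatenate(
        [draws[:, :n_half], draws[:, n_half:2 * n_half]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        warnings.warn("constant chains: PSRF defined as 1", RuntimeWarning)
        return 1.0
    B_over_n = halves.mean(axis=1).var(ddof=1)
    var_plus = (n_half - 1) / n_half * W + B_over_n
    return float(np.sqrt(var_plus / W))


def _psrf_all(draws: np.ndarray) -> np.ndarray:
    """Vectorized split-R-hat over (chains, iterations, params)."""
    C, n, k = draws.shape
    n_half = n // 2
    halves = np.concatenate(
        [draws[:, :n_half], draws[:, n_half:2 * n_half]], axis=0)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = halves.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n_half - 1) / n_half * W + B_over_n
    out = np.ones(k)
    nz = W > 0
    out[nz] = np.sqrt(var_plus[nz] / W[nz])
    return out


@dataclass
class PosteriorFit:
    """Retained draws plus everything model comparison and recovery need."""

    posterior: JointPosterior
    draws: np.ndarray                 # (chains, kept, n_params) unconstrained
    logp: np.ndarray                  # (chains, kept)
    prior: PriorConfig
    sampler: SamplerConfig
    psrf: np.ndarray                  # per flat unconstrained parameter
    chain_stats: List[dict]
    seed: int
    runtime_s: float
    ll_ra: Optional[np.ndarray] = None    # (total draws, N*m) float32
    ll_rt: Optional[np.ndarray] = None

    # -- basic accessors ----------------------------------------------------
    @property
    def spec(self) -> ModelSpec:
        return self.posterior.spec

    @property
    def pattern(self) -> LoadingPattern:
        return self.posterior.pattern

    @property
    def layout(self) -> ParamLayout:
        return self.posterior.layout

    @property
    def structure(self) -> ModelStructure:
        return self.posterior.structure

    @property
    def n_draws_total(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def max_psrf(self) -> float:
        return float(self.psrf.max())

    @property
    def converged(self) -> bool:
        return bool(self.max_psrf < self.sampler.psrf_threshold)

    @property
    def n_divergent(self) -> int:
        return int(sum(s["n_divergent"] for s in self.chain_stats))

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def constrained(self, name: str) -> np.ndarray:
        """All retained draws of one named block on its natural scale,
        stacked over chains: shape (draws, ...block shape)."""
        lay = self.layout
        st = self.structure
        s = lay.slices
        flat = self.flat_draws()
        if name in ("a_g", "alpha_g") and not st.G:
            return np.zeros((flat.shape[0], st.m))
        simple = {
            "a_g": ("log_a_g", np.exp), "a_s": ("log_a_s", np.exp),
            "alpha_g": ("log_alpha_g", np.exp), "alpha_s": ("log_alpha_s", np.exp),
            "lambda": ("log_lambda", np.exp), "d": ("d", None),
            "beta": ("beta", None), "rho": ("z_rho", np.tanh),
            "mu_d": ("mu_d", None), "mu_beta": ("mu_beta", None),
            "sigma_d": ("log_sigma_d", np.exp),
            "sigma_beta": ("log_sigma_beta", np.exp),
            "rho_d_beta": ("z_rho_d_beta", np.tanh),
        }
        if name == "sigma":
            return np.exp(-flat[:, s["log_lambda"]])
        if name == "theta":
            return flat[:, s["theta"]].reshape(-1, st.N, st.K_a)
        if name == "tau":
            return flat[:, s["tau"]].reshape(-1, st.N, st.K_t)
        if name not in simple:
            raise KeyError(name)
        key, f = simple[name]
        vals = flat[:, s[key]]
        if f is not None:
            vals = f(vals)
        return vals[:, 0] if vals.shape[1] == 1 else vals

    def eap(self, name: str) -> np.ndarray:
        """Posterior-mean (EAP) estimate of a named block."""
        return self.constrained(name).mean(axis=0)

    # -- pointwise log likelihood ------------------------------------------
    def _pointwise(self) -> None:
        if self.ll_ra is not None:
            return
        post = self.posterior
        st = post.structure
        u = post._u.astype(np.float64)
        obs_ra = post._u >= 0
        obs_rt = post._obs_rt.astype(bool)
        lnT = post._lnT
        flat = self.flat_draws()
        S = flat.shape[0]
        ll_ra = np.empty((S, st.N * st.m), dtype=np.float32)
        ll_rt = np.empty((S, st.N * st.m), dtype=np.float32)
        G = st.G
        log2pi = np.log(2 * np.pi)
        for s_ix, q in enumerate(flat):
            p = self.layout.unpack(q)
            theta_s = p["theta"][:, G + st.g_ra]
            eta = p["d"][None, :] + p["a_s"][None, :] * theta_s
            if G:
                eta = eta + p["a_g"][None, :] * p["theta"][:, 0][:, None]
            # log Bernoulli, stable
            abseta = np.abs(eta)
            lse = np.maximum(eta, 0) + np.log1p(np.exp(-abseta))
            ra = np.where(obs_ra, u * eta - lse, 0.0)
            tau_s = p["tau"][:, G + st.g_rt]
            mu = p["beta"][None, :] - p["alpha_s"][None, :] * tau_s
            if G:
                mu = mu - p["alpha_g"][None, :] * p["tau"][:, 0][:, None]
            lam = p["lambda"][None, :]
            z = (lnT - mu) * lam
            rt = np.where(obs_rt, np.log(lam) - 0.5 * log2pi - 0.5 * z * z, 0.0)
            ll_ra[s_ix] = ra.ravel()
            ll_rt[s_ix] = rt.ravel()
        self.ll_ra = ll_ra
        self.ll_rt = ll_rt

    def pointwise_loglik(self, component: str = "total") -> np.ndarray:
        """Draws x observations log-likelihood matrix.

        ``component`` is ``"ra"``, ``"rt"`` or ``"total"``; observations are
        person x item cells (RA and RT cells counted separately for the
        component matrices).  Missing cells are excluded.
        """
        self._pointwise()
        post = self.posterior
        obs_ra = (post._u >= 0).ravel()
        obs_rt = post._obs_rt.astype(bool).ravel()
        if component == "ra":
            return np.asarray(self.ll_ra)[:, obs_ra]
        if component == "rt":
            return np.asarray(self.ll_rt)[:, obs_rt]
        if component == "total":
            return np.concatenate(
                [np.asarray(self.ll_ra)[:, obs_ra],
                 np.asarray(self.ll_rt)[:, obs_rt]], axis=1)
        raise ValueError("component must be 'ra', 'rt' or 'total'")

    # -- summaries ----------------------------------------------------------
    def item_estimates(self) -> pd.DataFrame:
        """EAP item parameters, one row per item."""
        cols = {}
        for name in ("a_g", "a_s", "d", "alpha_g", "alpha_s", "lambda",
                     "sigma", "beta"):
            cols[name] = self.eap(name)
        return pd.DataFrame(cols)

    def person_estimates(self) -> Dict[str, np.ndarray]:
        """EAP trait matrices keyed 'theta' and 'tau' (columns: general
        first when present, then specifics)."""
        return {"theta": self.eap("theta"), "tau": self.eap("tau")}

    def summary(self, include_persons: bool = False) -> pd.DataFrame:
        """Posterior mean/sd/central 95% interval/PSRF per scalar parameter."""
        lay = self.layout
        st = self.structure
        rows = []
        flat = self.flat_draws()

        def block(name, transform, labels, sl):
            vals = transform(flat[:, sl])
            ps = self.psrf[sl]
            mean = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=1)
            lo, hi = np.percentile(vals, [2.5, 97.5], axis=0)
            for k, lab in enumerate(labels):
                rows.append((lab, mean[k], sd[k], lo[k], hi[k], ps[k]))

        ident = lambda x: x
        expt = np.exp
        tanh = np.tanh
        m = st.m
        if st.G:
            block("a_g", expt, [f"a_g[{j}]" for j in range(m)], lay.slices["log_a_g"])
            block("alpha_g", expt, [f"alpha_g[{j}]" for j in range(m)],
                  lay.slices["log_alpha_g"])
        block("a_s", expt, [f"a_s[{j}]" for j in range(m)], lay.slices["log_a_s"])
        block("d", ident, [f"d[{j}]" for j in range(m)], lay.slices["d"])
        block("alpha_s", expt, [f"alpha_s[{j}]" for j in range(m)],
              lay.slices["log_alpha_s"])
        block("lambda", expt, [f"one_over_sigma[{j}]" for j in range(m)],
              lay.slices["log_lambda"])
        block("beta", ident, [f"beta[{j}]" for j in range(m)], lay.slices["beta"])
        rho_labels = []
        for r in range(st.n_rho):
            kk, ss = st.rho_rows[r], st.rho_cols[r]
            rho_labels.append(f"rho_trait[{kk},{ss}]")
        if st.n_rho:
            block("rho", tanh, rho_labels, lay.slices["z_rho"])
        block("mu_d", ident, ["mu_d"], lay.slices["mu_d"])
        block("mu_beta", ident, ["mu_beta"], lay.slices["mu_beta"])
        block("sigma_d", expt, ["sigma_d"], lay.slices["log_sigma_d"])
        block("sigma_beta", expt, ["sigma_beta"], lay.slices["log_sigma_beta"])
        block("rho_d_beta", tanh, ["rho_d_beta"], lay.slices["z_rho_d_beta"])
        if include_persons:
            K_a, K_t = st.K_a, st.K_t
            labels = [f"theta[{i},{k}]" for i in range(st.N) for k in range(K_a)]
            block("theta", ident, labels, lay.slices["theta"])
            labels = [f"tau[{i},{k}]" for i in range(st.N) for k in range(K_t)]
            block("tau", ident, labels, lay.slices["tau"])
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                           "q2.5", "q97.5", "psrf"])


def fit(U: np.ndarray,
        T: np.ndarray,
        pattern: LoadingPattern,
        spec: ModelSpec = ModelSpec(),
        prior: PriorConfig = PriorConfig(),
        sampler: SamplerConfig = SamplerConfig(),
        compute_pointwise: bool = True) -> PosteriorFit:
    """Sample the joint posterior for one dataset and model variant.

    Runs ``sampler.chains`` NUTS chains from dispersed moderate-range random
    starts, retains thinned post-warmup draws, computes split-chain PSRF for
    every parameter and (optionally) the per-draw pointwise log-likelihood
    matrices used by WAIC/LOO.
    """
    t0 = time.perf_counter()
    post = JointPosterior(U, T, pattern, spec,
                          eta=prior.eta, mu_d_loc=prior.mu_d_loc,
                          mu_beta_loc=prior.mu_beta_loc,
                          mu_scale=prior.mu_d_scale)
    ss = np.random.SeedSequence(sampler.seed)
    chain_seeds = ss.spawn(sampler.chains)
    results: List[NutsResult] = []
    for c, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        q0 = post.initial_point(rng)
        logger.info("chain %d/%d: %d warmup + %d draws (thin %d)",
                    c + 1, sampler.chains, sampler.warmup,
                    sampler.draws_per_chain, sampler.thin)
        try:
            res = sample_nuts(
                post.logp_grad, q0, sampler.warmup, sampler.draws_per_chain,
                rng, target_accept=sampler.target_accept,
                max_treedepth=sampler.max_treedepth, thin=sampler.thin)
        except RuntimeError as exc:
            raise RuntimeError(f"sampler initialization failed on chain {c}: "
                               f"{exc}") from exc
        logger.info("chain %d done: accept=%.2f divergences=%d depth=%.1f",
                    c + 1, res.accept_rate, res.n_divergent, res.mean_treedepth)
        results.append(res)

    kept = min(r.draws.shape[0] for r in results)
    draws = np.stack([r.draws[:kept] for r in results])
    logp = np.stack([r.logp[:kept] for r in results])
    psrf = _psrf_all(draws)
    stats = [{
        "step_size": r.step_size,
        "n_divergent": r.n_divergent,
        "accept_rate": r.accept_rate,
        "mean_treedepth": r.mean_treedepth,
        "max_treedepth_hits": r.max_treedepth_hits,
    } for r in results]
    fit_ = PosteriorFit(posterior=post, draws=draws, logp=logp, prior=prior,
                        sampler=sampler, psrf=psrf, chain_stats=stats,
                        seed=sampler.seed, runtime_s=time.perf_counter() - t0)
    if not fit_.converged:
        logger.warning("non-converged fit: max PSRF %.3f >= %.2f",
                       fit_.max_psrf, sampler.psrf_threshold)
    if compute_pointwise:
        fit_._pointwise()
    fit_.runtime_s = time.perf_counter() - t0
    return fit_


def extract_structure(fit_: PosteriorFit) -> pd.DataFrame:
    """Posterior means and central 95% credible intervals of the level-2
    structure: ability--speed correlations (equal to covariances under the
    unit-variance identification), the (d, beta) moments, and the derived
    covariance ``sigma_d_beta``."""
    st = fit_.structure
    lay = fit_.layout
    flat = fit_.flat_draws()
    entries = {}
    rho = np.tanh(flat[:, lay.slices["z_rho"]])
    names = []
    if st.G:
        names.append("rho_theta_g_tau_g")
    if st.S_rt == st.S_ra:
        names += [f"rho_theta_s{s + 1}_tau_s{s + 1}" for s in range(st.S_ra)]
    else:
        names += [f"rho_theta_s{s + 1}_tau" for s in range(st.S_ra)]
    for k, nm in enumerate(names):
        entries[nm] = rho[:, k]
    entries["mu_d"] = flat[:, lay.slices["mu_d"]][:, 0]
    entries["mu_beta"] = flat[:, lay.slices["mu_beta"]][:, 0]
    sd = np.exp(flat[:, lay.slices["log_sigma_d"]][:, 0])
    sb = np.exp(flat[:, lay.slices["log_sigma_beta"]][:, 0])
    rdb = np.tanh(flat[:, lay.slices["z_rho_d_beta"]][:, 0])
    entries["sigma2_d"] = sd ** 2
    entries["sigma2_beta"] = sb ** 2
    entries["sigma_d_beta"] = rdb * sd * sb
    entries["rho_d_beta"] = rdb
    rows = []
    for nm, v in entries.items():
        lo, hi = np.percentile(v, [2.5, 97.5])
        rows.append((nm, float(v.mean()), float(v.std(ddof=1)),
                     float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                       "q2.5", "q97.5"])
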