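"""Joint log posterior of the hierarchical model family, with analytic
gradients, on an unconstrained parameter vector.

Parameterization (all variants share one layout; absent blocks have size 0):

* positive item parameters (``a_g, a_s, alpha_g, alpha_s, 1/sigma``) are
  sampled on the log scale with their half-normal priors plus the exp
  Jacobian;
* ``d`` and ``beta`` are unconstrained with the hierarchical bivariate
  normal prior (free means/scales, LKJ(1)-uniform correlation);
* person traits enter through the conditional factorization
  ``theta ~ N(0, I)``, ``tau_k | theta ~ N(sum_s P[k,s] theta_s, 1 -
  ||P[k,:]||^2)`` which reproduces unit marginal variances and puts the
  ability--speed correlations directly in ``P``.  For paired factors ``P``
  has one entry per pair; for a single speed dimension against several
  abilities (PMHM) the row holds one correlation per ability, with the
  positive-definiteness barrier arising naturally from ``log c_k``;
* correlations use atanh coordinates with the log(1-rho^2) Jacobian, i.e.
  a Uniform(-1, 1) prior (the 2x2 LKJ(1) case).

The numba kernel is the only hot path in the package; a finite-difference
test and an independent scipy-based log-posterior guard its correctness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from numba import njit

from .models import LoadingPattern, ModelSpec

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelStructure:
    """Shapes and index maps tying a dataset to a model variant."""

    N: int
    m: int
    G: int                      # 1 if general factors present else 0
    S_ra: int                   # specific ability dimensions
    S_rt: int                   # specific speed dimensions
    g_ra: np.ndarray            # item -> ability specific dim (0-based)
    g_rt: np.ndarray            # item -> speed specific dim
    rho_rows: np.ndarray        # speed-dim row of each correlation in P
    rho_cols: np.ndarray        # ability-dim column of each correlation

    @classmethod
    def build(cls, N: int, pattern: LoadingPattern, spec: ModelSpec) -> "ModelStructure":
        G = 1 if spec.has_general else 0
        S_ra = spec.n_ability_specific(pattern)
        S_rt = spec.n_speed_specific(pattern)
        g_ra = spec.ability_group_of(pattern).astype(np.int64)
        g_rt = spec.speed_group_of(pattern).astype(np.int64)
        rows, cols = [], []
        if G:
            rows.append(0)
            cols.append(0)
        if S_rt == S_ra:
            for s in range(S_ra):
                rows.append(G + s)
                cols.append(G + s)
        elif S_rt == 1:
            # single speed factor correlated with every ability factor
            for s in range(S_ra):
                rows.append(G)
                cols.append(G + s)
        else:  # pragma: no cover - no variant produces this
            raise ValueError("unsupported ability/speed dimension combination")
        return cls(N=N, m=pattern.n_items, G=G, S_ra=S_ra, S_rt=S_rt,
                   g_ra=g_ra, g_rt=g_rt,
                   rho_rows=np.asarray(rows, dtype=np.int64),
                   rho_cols=np.asarray(cols, dtype=np.int64))

    @property
    def K_a(self) -> int:
        return self.G + self.S_ra

    @property
    def K_t(self) -> int:
        return self.G + self.S_rt

    @property
    def n_rho(self) -> int:
        return self.rho_rows.shape[0]


class ParamLayout:
    """Offsets of each named block inside the flat unconstrained vector."""

    def __init__(self, st: ModelStructure):
        self.st = st
        m, N, G = st.m, st.N, st.G
        self.slices: Dict[str, slice] = {}
        o = 0
        for name, size in (
            ("log_a_g", m * G), ("log_a_s", m), ("d", m),
            ("log_alpha_g", m * G), ("log_alpha_s", m),
            ("log_lambda", m), ("beta", m),
            ("theta", N * st.K_a), ("tau", N * st.K_t),
            ("z_rho", st.n_rho),
            ("mu_d", 1), ("mu_beta", 1),
            ("log_sigma_d", 1), ("log_sigma_beta", 1), ("z_rho_d_beta", 1),
        ):
            self.slices[name] = slice(o, o + size)
            o += size
        self.n_params = o

    def unpack(self, q: np.ndarray) -> Dict[str, np.ndarray]:
        """Constrained, named view of one draw (copies, natural scales)."""
        st = self.st
        s = self.slices
        out: Dict[str, np.ndarray] = {}
        m = st.m
        if st.G:
            out["a_g"] = np.exp(q[s["log_a_g"]])
            out["alpha_g"] = np.exp(q[s["log_alpha_g"]])
        else:
            out["a_g"] = np.zeros(m)
            out["alpha_g"] = np.zeros(m)
        out["a_s"] = np.exp(q[s["log_a_s"]])
        out["alpha_s"] = np.exp(q[s["log_alpha_s"]])
        out["d"] = q[s["d"]].copy()
        out["beta"] = q[s["beta"]].copy()
        out["lambda"] = np.exp(q[s["log_lambda"]])
        out["sigma"] = 1.0 / out["lambda"]
        out["theta"] = q[s["theta"]].reshape(st.N, st.K_a).copy()
        out["tau"] = q[s["tau"]].reshape(st.N, st.K_t).copy()
        out["rho"] = np.tanh(q[s["z_rho"]])
        out["mu_d"] = float(q[s["mu_d"]][0])
        out["mu_beta"] = float(q[s["mu_beta"]][0])
        out["sigma_d"] = float(np.exp(q[s["log_sigma_d"]][0]))
        out["sigma_beta"] = float(np.exp(q[s["log_sigma_beta"]][0]))
        out["rho_d_beta"] = float(np.tanh(q[s["z_rho_d_beta"]][0]))
        return out

    def parameter_names(self) -> Dict[str, int]:
        """Block name -> flat size (diagnostics bookkeeping)."""
        return {k: v.stop - v.start for k, v in self.slices.items()
                if v.stop > v.start}


@njit(cache=True)
def _logp_grad_kernel(q, u, lnT, obs_rt, g_ra, g_rt, G, S_ra, S_rt,
                      rho_rows, rho_cols, eta, mu_d_loc, mu_b_loc,
                      mu_sd):  # pragma: no cover - exercised via wrapper
    N, m = u.shape
    K_a = G + S_ra
    K_t = G + S_rt
    n_rho = rho_rows.shape[0]

    # ---- offsets (must mirror ParamLayout) ----
    o = 0
    o_lag = o; o += m * G
    o_las = o; o += m
    o_d = o; o += m
    o_lAg = o; o += m * G
    o_lAs = o; o += m
    o_llam = o; o += m
    o_beta = o; o += m
    o_th = o; o += N * K_a
    o_ta = o; o += N * K_t
    o_zr = o; o += n_rho
    o_mud = o; o += 1
    o_mub = o; o += 1
    o_lsd = o; o += 1
    o_lsb = o; o += 1
    o_zdb = o; o += 1
    n_par = o

    grad = np.zeros(n_par)

    # ---- transforms ----
    a_g = np.empty(m)
    A_g = np.empty(m)
    for j in range(m):
        if G:
            a_g[j] = np.exp(q[o_lag + j])
            A_g[j] = np.exp(q[o_lAg + j])
        else:
            a_g[j] = 0.0
            A_g[j] = 0.0
    a_s = np.exp(q[o_las:o_las + m])
    d = q[o_d:o_d + m]
    A_s = np.exp(q[o_lAs:o_lAs + m])
    lam = np.exp(q[o_llam:o_llam + m])
    log_lam = q[o_llam:o_llam + m]
    beta = q[o_beta:o_beta + m]
    mu_d = q[o_mud]
    mu_b = q[o_mub]
    sd = np.exp(q[o_lsd])
    sb = np.exp(q[o_lsb])
    rdb = np.tanh(q[o_zdb])

    # reject states pushed to the edge of the constrained space by large
    # leapfrog excursions (exp under/overflow, |rho| -> 1)
    for j in range(m):
        ok_j = (a_s[j] > 0.0 and np.isfinite(a_s[j])
                and A_s[j] > 0.0 and np.isfinite(A_s[j])
                and lam[j] > 0.0 and np.isfinite(lam[j]))
        if G:
            ok_j = ok_j and np.isfinite(a_g[j]) and np.isfinite(A_g[j])
        if not ok_j:
            return -np.inf, grad
    if not (sd > 0.0 and np.isfinite(sd) and sb > 0.0 and np.isfinite(sb)
            and 1.0 - rdb * rdb > 1e-15):
        return -np.inf, grad

    P = np.zeros((K_t, K_a))
    rho = np.tanh(q[o_zr:o_zr + n_rho])
    for r in range(n_rho):
        P[rho_rows[r], rho_cols[r]] = rho[r]
    c = np.empty(K_t)
    ok = True
    for k in range(K_t):
        acc = 1.0
        for s2 in range(K_a):
            acc -= P[k, s2] * P[k, s2]
        c[k] = acc
        if acc <= 1e-12:
            ok = False
    if not ok:
        return -np.inf, grad

    lp = 0.0
    gag = np.zeros(m)
    gas = np.zeros(m)
    gd = np.zeros(m)
    gAg = np.zeros(m)
    gAs = np.zeros(m)
    glam = np.zeros(m)
    gbeta = np.zeros(m)

    # ---- level-1 likelihoods ----
    for i in range(N):
        thb = o_th + i * K_a
        tab = o_ta + i * K_t
        for j in range(m):
            uu = u[i, j]
            if uu >= 0:
                sa = G + g_ra[j]   # item's specific ability column
                th_s = q[thb + sa]
                lin = d[j] + a_s[j] * th_s
                if G:
                    lin += a_g[j] * q[thb]
                if lin > 0.0:
                    ex = np.exp(-lin)
                    lse = lin + np.log1p(ex)
                    pr = 1.0 / (1.0 + ex)
                else:
                    ex = np.exp(lin)
                    lse = np.log1p(ex)
                    pr = ex / (1.0 + ex)
                lp += uu * lin - lse
                res = uu - pr
                gd[j] += res
                gas[j] += res * th_s
                grad[thb + sa] += res * a_s[j]
                if G:
                    gag[j] += res * q[thb]
                    grad[thb] += res * a_g[j]
            if obs_rt[i, j]:
                st_ = G + g_rt[j]
                ta_s = q[tab + st_]
                e = lnT[i, j] - beta[j] + A_s[j] * ta_s
                if G:
                    e += A_g[j] * q[tab]
                le = lam[j] * e
                lp += log_lam[j] - 0.5 * _LOG_2PI - 0.5 * le * le
                w = lam[j] * le           # = lam^2 * e
                gbeta[j] += w
                gAs[j] -= w * ta_s
                grad[tab + st_] -= w * A_s[j]
                if G:
                    gAg[j] -= w * q[tab]
                    grad[tab] -= w * A_g[j]
                glam[j] += 1.0 / lam[j] - lam[j] * e * e

    # ---- person trait prior (theta iid N(0,1); tau | theta conditional) ----
    accP = np.zeros((K_t, K_a))
    accC = np.zeros(K_t)
    for i in range(N):
        thb = o_th + i * K_a
        tab = o_ta + i * K_t
        for s2 in range(K_a):
            th_v = q[thb + s2]
            lp += -0.5 * th_v * th_v - 0.5 * _LOG_2PI
            grad[thb + s2] += -th_v
        for k in range(K_t):
            mean = 0.0
            for s2 in range(K_a):
                if P[k, s2] != 0.0:
                    mean += P[k, s2] * q[thb + s2]
            w = q[tab + k] - mean
            lp += -0.5 * np.log(c[k]) - 0.5 * w * w / c[k] - 0.5 * _LOG_2PI
            grad[tab + k] += -w / c[k]
            for s2 in range(K_a):
                if P[k, s2] != 0.0:
                    grad[thb + s2] += (w / c[k]) * P[k, s2]
                    accP[k, s2] += (w / c[k]) * q[thb + s2]
            accC[k] += -0.5 / c[k] + 0.5 * w * w / (c[k] * c[k])

    for r in range(n_rho):
        k = rho_rows[r]
        s2 = rho_cols[r]
        dlp_dP = accP[k, s2] - 2.0 * P[k, s2] * accC[k]
        rr = rho[r]
        # LKJ(eta) on the 2x2 block (eta=1: uniform) plus atanh Jacobian
        lp += eta * np.log(1.0 - rr * rr)
        grad[o_zr + r] += dlp_dP * (1.0 - rr * rr) - 2.0 * eta * rr

    # ---- (d, beta) hierarchical prior ----
    c2 = 1.0 - rdb * rdb
    acc_sd = 0.0
    acc_sb = 0.0
    acc_r = 0.0
    g_mud = 0.0
    g_mub = 0.0
    for j in range(m):
        xt = (d[j] - mu_d) / sd
        yt = (beta[j] - mu_b) / sb
        A = xt * xt - 2.0 * rdb * xt * yt + yt * yt
        lp += -np.log(sd) - np.log(sb) - 0.5 * np.log(c2) - 0.5 * A / c2 - _LOG_2PI
        Qx = (xt - rdb * yt) / c2
        Qy = (yt - rdb * xt) / c2
        gd[j] += -Qx / sd
        gbeta[j] += -Qy / sb
        g_mud += Qx / sd
        g_mub += Qy / sb
        acc_sd += -1.0 + Qx * xt
        acc_sb += -1.0 + Qy * yt
        acc_r += rdb / c2 + xt * yt / c2 - A * rdb / (c2 * c2)

    # ---- item priors (half-normal on positive scales) + chain rules ----
    for j in range(m):
        if G:
            lp += -0.5 * a_g[j] * a_g[j] + q[o_lag + j]
            grad[o_lag + j] = gag[j] * a_g[j] + 1.0 - a_g[j] * a_g[j]
            lp += -0.5 * A_g[j] * A_g[j] + q[o_lAg + j]
            grad[o_lAg + j] = gAg[j] * A_g[j] + 1.0 - A_g[j] * A_g[j]
        lp += -0.5 * a_s[j] * a_s[j] + q[o_las + j]
        grad[o_las + j] = gas[j] * a_s[j] + 1.0 - a_s[j] * a_s[j]
        lp += -0.5 * A_s[j] * A_s[j] + q[o_lAs + j]
        grad[o_lAs + j] = gAs[j] * A_s[j] + 1.0 - A_s[j] * A_s[j]
        lp += -0.5 * lam[j] * lam[j] + q[o_llam + j]
        grad[o_llam + j] = glam[j] * lam[j] + 1.0 - lam[j] * lam[j]
        grad[o_d + j] = gd[j]
        grad[o_beta + j] = gbeta[j]

    # ---- hyper-priors ----
    lp += -0.5 * ((mu_d - mu_d_loc) / mu_sd) ** 2
    g_mud += -(mu_d - mu_d_loc) / (mu_sd * mu_sd)
    lp += -0.5 * ((mu_b - mu_b_loc) / mu_sd) ** 2
    g_mub += -(mu_b - mu_b_loc) / (mu_sd * mu_sd)
    grad[o_mud] = g_mud
    grad[o_mub] = g_mub
    lp += -0.5 * sd * sd + q[o_lsd]
    grad[o_lsd] = acc_sd + 1.0 - sd * sd
    lp += -0.5 * sb * sb + q[o_lsb]
    grad[o_lsb] = acc_sb + 1.0 - sb * sb
    lp += eta * np.log(c2)
    grad[o_zdb] = acc_r * c2 - 2.0 * eta * rdb

    if not np.isfinite(lp):
        return -np.inf, grad
    return lp, grad


class JointPosterior:
    """Callable log posterior for one dataset under one model variant."""

    def __init__(self, U: np.ndarray, T: np.ndarray, pattern: LoadingPattern,
                 spec: ModelSpec, *, eta: float = 1.0, mu_d_loc: float = 0.0,
                 mu_beta_loc: float = 4.0, mu_scale: float = 0.5):
        U = np.asarray(U, dtype=float)
        T = np.asarray(T, dtype=float)
        N, m = U.shape
        if T.shape != (N, m):
            raise ValueError("U and T shapes disagree")
        obs_ra = ~np.isnan(U)
        if not np.isin(U[obs_ra], (0.0, 1.0)).all():
            raise ValueError("responses must be 0, 1 or missing (NaN)")
        obs_rt = ~np.isnan(T)
        if (T[obs_rt] <= 0).any():
            raise ValueError("response times must be strictly positive")
        self.structure = ModelStructure.build(N, pattern, spec)
        self.layout = ParamLayout(self.structure)
        self.pattern = pattern
        self.spec = spec
        u8 = np.where(obs_ra, U, -1.0).astype(np.int8)
        self._u = np.ascontiguousarray(u8)
        self._lnT = np.ascontiguousarray(
            np.where(obs_rt, np.log(np.where(obs_rt, T, 1.0)), 0.0))
        self._obs_rt = np.ascontiguousarray(obs_rt.astype(np.uint8))
        if eta <= 0 or mu_scale <= 0:
            raise ValueError("eta and mu_scale must be positive")
        self._hyper = (float(eta), float(mu_d_loc), float(mu_beta_loc),
                       float(mu_scale))

    @property
    def n_params(self) -> int:
        return self.layout.n_params

    def logp_grad(self, q: np.ndarray):
        st = self.structure
        return _logp_grad_kernel(
            q, self._u, self._lnT, self._obs_rt, st.g_ra, st.g_rt,
            st.G, st.S_ra, st.S_rt, st.rho_rows, st.rho_cols, *self._hyper)

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Dispersed initialization near moment estimates.

        Loadings start at moderate random values in (0.2, 1.5) away from the
        truncation boundary; ``d``, ``beta`` and the time discrimination
        start at jittered per-item moment estimates (logit of the observed
        proportion correct, mean and reciprocal SD of observed log times),
        which keeps short adaptation phases out of the far tails where
        high-precision items can trap a chain.
        """
        lay = self.layout
        st = self.structure
        q = np.zeros(lay.n_params)
        s = lay.slices

        def put(name, values):
            q[s[name]] = values

        m, N = st.m, st.N
        obs_ra = self._u >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            pbar = np.where(obs_ra, self._u, 0).sum(axis=0) / \
                np.maximum(obs_ra.sum(axis=0), 1)
            d0 = np.log(np.clip(pbar, 0.05, 0.95) /
                        (1 - np.clip(pbar, 0.05, 0.95)))
        obs_rt = self._obs_rt.astype(bool)
        n_rt = np.maximum(obs_rt.sum(axis=0), 2)
        beta0 = np.where(obs_rt, self._lnT, 0).sum(axis=0) / n_rt
        var0 = np.where(obs_rt, (self._lnT - beta0[None, :]) ** 2,
                        0).sum(axis=0) / (n_rt - 1)
        lam0 = 1.0 / np.sqrt(np.clip(var0, 1e-4, None))

        if st.G:
            put("log_a_g", np.log(rng.uniform(0.2, 1.5, m)))
            put("log_alpha_g", np.log(rng.uniform(0.2, 1.5, m)))
        put("log_a_s", np.log(rng.uniform(0.2, 1.5, m)))
        put("log_alpha_s", np.log(rng.uniform(0.2, 1.5, m)))
        put("log_lambda", np.log(lam0) + rng.uniform(-0.1, 0.3, m))
        put("d", d0 + rng.uniform(-0.3, 0.3, m))
        put("beta", beta0 + rng.uniform(-0.3, 0.3, m))

        # crude standardized person scores as trait warm starts: overall
        # scores for the general factors, per-group scores for specifics
        def std_scores(values, obs, cols):
            x = np.where(obs[:, cols], values[:, cols], 0).sum(axis=1) / \
                np.maximum(obs[:, cols].sum(axis=1), 1)
            return (x - x.mean()) / max(x.std(), 1e-6)

        u_f = self._u.astype(np.float64)
        dev = self._lnT - beta0[None, :]
        all_cols = np.arange(m)
        theta0 = np.empty((N, st.K_a))
        tau0 = np.empty((N, st.K_t))
        if st.G:
            theta0[:, 0] = std_scores(u_f, obs_ra, all_cols)
            tau0[:, 0] = -std_scores(dev, obs_rt, all_cols)
        for sdim in range(st.S_ra):
            cols = np.flatnonzero(st.g_ra == sdim)
            theta0[:, st.G + sdim] = std_scores(u_f, obs_ra, cols)
        for sdim in range(st.S_rt):
            cols = np.flatnonzero(st.g_rt == sdim)
            tau0[:, st.G + sdim] = -std_scores(dev, obs_rt, cols)
        put("theta", (0.7 * theta0 + rng.uniform(-0.5, 0.5, (N, st.K_a))).ravel())
        put("tau", (0.7 * tau0 + rng.uniform(-0.5, 0.5, (N, st.K_t))).ravel())
        put("z_rho", rng.uniform(-0.2, 0.2, st.n_rho))
        put("mu_d", 0.0)
        put("mu_beta", 4.0)
        put("log_sigma_d", 0.0)
        put("log_sigma_beta", np.log(0.5))
        put("z_rho_d_beta", 0.0)
        return q
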