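"""A self-contained No-U-Turn sampler.

Multinomial NUTS with tree doubling, dual-averaging step-size adaptation and
windowed diagonal mass-matrix estimation during warmup.  The sampler is
generic: it only needs a function returning the log density and its gradient
on an unconstrained parameter vector.

Conventions: kinetic energy ``0.5 * p' M^{-1} p`` with diagonal mass ``M``;
``inv_mass`` is adapted towards the posterior marginal variances.  A proposed
state whose energy error exceeds ``divergence_threshold`` marks the
transition divergent and stops the current trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = ["sample_nuts", "NutsResult"]

logger = logging.getLogger(__name__)

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    """Draws and diagnostics from one chain."""

    draws: np.ndarray            # (n_kept, dim) post-warmup, thinned
    logp: np.ndarray             # (n_kept,)
    step_size: float
    inv_mass: np.ndarray
    n_divergent: int
    accept_rate: float
    mean_treedepth: float
    max_treedepth_hits: int


class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance delta)."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_stat: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # shrink towards a small constant (keeps the metric well conditioned)
        w = self.n / (self.n + 5.0)
        return w * var + 1e-3 * (1 - w)


class _Tree:
    """One sub-trajectory: edge states, multinomial weight, proposal."""

    __slots__ = ("q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
                 "q_prop", "g_prop", "logp_prop", "log_sum_w", "sum_p",
                 "sum_accept", "n_leapfrog", "diverging", "turning")


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * inv_mass * p1
    logp1, grad1 = logp_grad(q1)
    p1 = p1 + 0.5 * eps * grad1
    return q1, p1, logp1, grad1


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p * inv_mass, p))


def _is_turning(q_minus, p_minus, q_plus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _build_leaf(logp_grad, q, p, grad, v, eps, inv_mass, h0, rng) -> _Tree:
    q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, v * eps, inv_mass)
    t = _Tree()
    t.q_minus = t.q_plus = q1
    t.p_minus = t.p_plus = p1
    t.g_minus = t.g_plus = grad1
    t.q_prop = q1
    t.g_prop = grad1
    t.logp_prop = logp1
    if np.isfinite(logp1):
        h1 = -logp1 + _kinetic(p1, inv_mass)
        delta = h0 - h1
    else:
        delta = -np.inf
    t.log_sum_w = delta
    t.sum_p = p1.copy()
    t.sum_accept = min(1.0, math.exp(min(0.0, delta)))
    t.n_leapfrog = 1
    t.diverging = (not np.isfinite(delta)) or (-delta > _DIVERGENCE_THRESHOLD)
    t.turning = False
    return t


def _build_tree(logp_grad, q, p, grad, v, depth, eps, inv_mass, h0, rng) -> _Tree:
    if depth == 0:
        return _build_leaf(logp_grad, q, p, grad, v, eps, inv_mass, h0, rng)
    first = _build_tree(logp_grad, q, p, grad, v, depth - 1, eps, inv_mass, h0, rng)
    if first.diverging or first.turning:
        return first
    if v > 0:
        second = _build_tree(logp_grad, first.q_plus, first.p_plus, first.g_plus,
                             v, depth - 1, eps, inv_mass, h0, rng)
        first.q_plus = second.q_plus
        first.p_plus = second.p_plus
        first.g_plus = second.g_plus
    else:
        second = _build_tree(logp_grad, first.q_minus, first.p_minus, first.g_minus,
                             v, depth - 1, eps, inv_mass, h0, rng)
        first.q_minus = second.q_minus
        first.p_minus = second.p_minus
        first.g_minus = second.g_minus
    first.sum_accept += second.sum_accept
    first.n_leapfrog += second.n_leapfrog
    first.diverging = second.diverging
    if not second.diverging:
        total = np.logaddexp(first.log_sum_w, second.log_sum_w)
        # multinomial sampling within the subtree
        if math.log(rng.uniform()) < second.log_sum_w - total:
            first.q_prop = second.q_prop
            first.g_prop = second.g_prop
            first.logp_prop = second.logp_prop
        first.log_sum_w = total
        first.sum_p = first.sum_p + second.sum_p
        first.turning = second.turning or _is_turning(
            first.q_minus, first.p_minus, first.q_plus, first.p_plus, inv_mass)
    return first


def _find_initial_step_size(logp_grad, q0, inv_mass, rng, eps: float = 1.0) -> float:
    logp0, grad0 = logp_grad(q0)
    p0 = rng.standard_normal(q0.shape) / np.sqrt(inv_mass)
    h0 = -logp0 + _kinetic(p0, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_grad, q0, p0, grad0, eps, inv_mass)
    h1 = -logp1 + _kinetic(p1, inv_mass) if np.isfinite(logp1) else np.inf
    delta = h0 - h1
    direction = 1 if delta > math.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_grad, q0, p0, grad0, eps, inv_mass)
        h1 = -logp1 + _kinetic(p1, inv_mass) if np.isfinite(logp1) else np.inf
        delta = h0 - h1
        if (direction == 1 and delta <= math.log(0.5)) or \
           (direction == -1 and delta >= math.log(0.5)):
            break
    return eps


def sample_nuts(
    logp_grad: Callable[[np.ndarray], Tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    adapt_mass: bool = True,
    thin: int = 1,
    store_logp: bool = True,
) -> NutsResult:
    """Run one NUTS chain and return thinned post-warmup draws.

    ``n_draws`` counts post-warmup *iterations*; ``draws`` keeps every
    ``thin``-th of them.
    """
    dim = q0.shape[0]
    q = np.array(q0, dtype=float)
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise RuntimeError("non-finite log density at the initial point")
    inv_mass = np.ones(dim)
    eps = _find_initial_step_size(logp_grad, q, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)

    # Stan-style warmup phases: step-size buffer, doubling variance windows,
    # terminal step-size buffer.
    if adapt_mass and n_warmup >= 40:
        init_buf = max(int(0.15 * n_warmup), 10)
        term_buf = max(int(0.10 * n_warmup), 10)
        window_ends = []
        start, size = init_buf, max(int(0.25 * n_warmup), 25)
        while start + size < n_warmup - term_buf:
            window_ends.append(start + size)
            start += size
            size *= 2
        window_ends.append(n_warmup - term_buf)
    else:
        window_ends = []
    welford: Optional[_Welford] = _Welford(dim) if window_ends else None
    win_idx = 0

    n_kept = (n_draws + thin - 1) // thin
    draws = np.empty((n_kept, dim))
    logps = np.empty(n_kept)
    n_div = 0
    acc_sum = 0.0
    depth_sum = 0
    max_hits = 0
    kept = 0

    total_iters = n_warmup + n_draws
    for it in range(total_iters):
        warm = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -logp + _kinetic(p0, inv_mass)
        tree = None
        q_minus = q_plus = q
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        log_sum_w = 0.0
        sum_p = p0.copy()
        q_prop, g_prop, logp_prop = q, grad, logp
        accept_stat = 0.0
        n_leap = 0
        depth = 0
        diverged = False
        while depth < max_treedepth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v > 0:
                sub = _build_tree(logp_grad, q_plus, p_plus, g_plus, v, depth,
                                  eps, inv_mass, h0, rng)
                if not (sub.diverging or sub.turning):
                    q_plus, p_plus, g_plus = sub.q_plus, sub.p_plus, sub.g_plus
            else:
                sub = _build_tree(logp_grad, q_minus, p_minus, g_minus, v, depth,
                                  eps, inv_mass, h0, rng)
                if not (sub.diverging or sub.turning):
                    q_minus, p_minus, g_minus = sub.q_minus, sub.p_minus, sub.g_minus
            accept_stat += sub.sum_accept
            n_leap += sub.n_leapfrog
            if sub.diverging:
                diverged = True
                break
            if sub.turning:
                break
            # biased progressive sampling: favour the fresh subtree
            if math.log(rng.uniform()) < sub.log_sum_w - log_sum_w:
                q_prop, g_prop, logp_prop = sub.q_prop, sub.g_prop, sub.logp_prop
            log_sum_w = np.logaddexp(log_sum_w, sub.log_sum_w)
            sum_p = sum_p + sub.sum_p
            depth += 1
            if _is_turning(q_minus, p_minus, q_plus, p_plus, inv_mass):
                break
        else:
            max_hits += 1

        q = q_prop
        logp = logp_prop
        grad = g_prop
        accept_mean = accept_stat / max(n_leap, 1)

        if warm:
            eps = da.update(accept_mean)
            if welford is not None and it >= max(int(0.15 * n_warmup), 10):
                welford.push(q)
                if win_idx < len(window_ends) and it + 1 == window_ends[win_idx]:
                    inv_mass = welford.variance()
                    welford = _Welford(dim)
                    win_idx += 1
                    eps = _find_initial_step_size(logp_grad, q, inv_mass, rng,
                                                  eps=da.adapted)
                    da = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            if diverged:
                n_div += 1
            acc_sum += accept_mean
            depth_sum += depth
            k = it - n_warmup
            if k % thin == 0:
                draws[kept] = q
                logps[kept] = logp
                kept += 1

    return NutsResult(
        draws=draws[:kept],
        logp=logps[:kept],
        step_size=eps,
        inv_mass=inv_mass,
        n_divergent=n_div,
        accept_rate=acc_sum / max(n_draws, 1),
        mean_treedepth=depth_sum / max(n_draws, 1),
        max_treedepth_hits=max_hits,
    )
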