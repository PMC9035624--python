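"""Level-1 likelihood pieces and the loading-pattern/model-variant types."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from bfirt.models import (
    ItemParameters,
    LoadingPattern,
    ModelSpec,
    ModelVariant,
    PersonParameters,
    irt_prob,
    log_rt_logdensity,
    log_rt_mean,
    pointwise_loglik,
)
from bfirt.simulate import SimConfig, simulate_dataset

finite = st.floats(-5, 5, allow_nan=False)


class TestLoadingPattern:
    def test_block_pattern_indicator(self):
        p = LoadingPattern.from_blocks([10, 10, 10])
        S = p.indicator_matrix()
        assert S.shape == (30, 3)
        assert (S.sum(axis=1) == 1).all()
        # contiguous 10/10/10 block structure
        assert (S[:10, 0] == 1).all() and (S[10:20, 1] == 1).all() \
            and (S[20:, 2] == 1).all()
        assert S.sum() == 30

    @pytest.mark.parametrize("kwargs", [
        dict(n_items=3, n_specific=2, group_of=[0, 0, 2]),   # bad index
        dict(n_items=3, n_specific=2, group_of=[0, 0, 0]),   # empty dim
        dict(n_items=3, n_specific=2, group_of=[0, 1]),      # wrong length
        dict(n_items=0, n_specific=1, group_of=[]),          # no items
    ])
    def test_invalid_patterns_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LoadingPattern(**{k: np.asarray(v) if k == "group_of" else v
                              for k, v in kwargs.items()})


class TestIrtProb:
    def test_zero_predictor_is_half(self):
        assert irt_prob(0.0, 1.0, 1.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_logistic_value(self):
        # d + a_g*theta_g + a_s*theta_s = 0.5 + 1.2 - 0.4 = 1.3
        expected = 1.0 / (1.0 + np.exp(-1.3))   # scalar logistic oracle
        assert irt_prob(0.5, 1.2, 0.8, 1.0, -0.5) == pytest.approx(expected,
                                                                   abs=1e-14)

    @given(d=finite, a_g=st.floats(0, 3), a_s=st.floats(0, 3),
           tg=finite, ts=finite)
    @settings(max_examples=100, derandomize=True)
    def test_symmetry(self, d, a_g, a_s, tg, ts):
        p1 = irt_prob(d, a_g, a_s, tg, ts)
        p2 = irt_prob(-d, a_g, a_s, -tg, -ts)
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_traits(self):
        grid = np.linspace(-4, 4, 41)
        p_g = irt_prob(0.3, 1.1, 0.7, grid, 0.2)
        p_s = irt_prob(0.3, 1.1, 0.7, 0.2, grid)
        assert (np.diff(p_g) > 0).all()
        assert (np.diff(p_s) > 0).all()

    def test_extreme_predictor_stable(self):
        assert irt_prob(700.0, 0.0, 1.0, 0.0, 0.0) == pytest.approx(1.0)
        assert irt_prob(-700.0, 0.0, 1.0, 0.0, 0.0) == pytest.approx(0.0)


class TestLogRt:
    def test_zero_slopes(self):
        assert log_rt_mean(4.0, 0.0, 0.0, 3.0, -2.0) == pytest.approx(4.0)

    def test_arithmetic(self):
        assert log_rt_mean(4.0, 0.5, 0.3, 1.0, 0.0) == pytest.approx(3.5)

    def test_monotone_decreasing_in_speed(self):
        taus = np.linspace(-3, 3, 25)
        means = log_rt_mean(4.0, 0.5, 0.3, taus, 0.0)
        assert (np.diff(means) < 0).all()

    def test_standard_normal_peak(self):
        # ln t = 4 = mean, sigma = 1: density of N(0,1) at 0
        val = log_rt_logdensity(np.exp(4.0), 4.0, 0.0, 0.0, 1.0, 0.7, -1.2)
        assert val == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)), abs=1e-12)

    def test_integrates_to_one_on_log_scale(self):
        beta, ag, as_, sig, tg, ts = 3.2, 0.6, 0.4, 0.8, 0.5, -0.3
        x = np.linspace(-8, 8, 4001) + log_rt_mean(beta, ag, as_, tg, ts)
        dens = np.exp(log_rt_logdensity(np.exp(x), beta, ag, as_, sig, tg, ts))
        assert integrate.trapezoid(dens, x) == pytest.approx(1.0, abs=1e-4)

    def test_brute_force_normal_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            beta = rng.normal(4, 1)
            ag, as_, sig = rng.uniform(0.1, 2, 3)
            tg, ts = rng.normal(size=2)
            t = rng.uniform(0.2, 200.0)
            mu = beta - ag * tg - as_ * ts
            z = (np.log(t) - mu) / sig
            oracle = -0.5 * z * z - np.log(sig * np.sqrt(2 * np.pi))
            got = log_rt_logdensity(t, beta, ag, as_, sig, tg, ts)
            assert got == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("t,sig", [(0.0, 1.0), (-3.0, 1.0), (1.0, 0.0),
                                       (1.0, -0.5)])
    def test_domain_violations(self, t, sig):
        with pytest.raises(ValueError):
            log_rt_logdensity(t, 4.0, 0.5, 0.5, sig, 0.0, 0.0)


def _toy(N=11, m=6, seed=5):
    cfg = SimConfig(N=N, m=m, n_specific=3, seed=seed)
    U, T, truth = simulate_dataset(cfg)
    return cfg, U.astype(float), T, truth


class TestPointwiseLoglik:
    def test_forced_half_probability(self):
        cfg, U, T, truth = _toy()
        m = cfg.m
        items = ItemParameters(
            a_g=np.full(m, 1e-12), a_s=np.full(m, 1e-12), d=np.zeros(m),
            alpha_g=truth.items.alpha_g, alpha_s=truth.items.alpha_s,
            beta=truth.items.beta, sigma=truth.items.sigma)
        pl = pointwise_loglik(U, T, items, truth.persons, cfg.pattern)
        assert pl.ra.sum() == pytest.approx(cfg.N * m * np.log(0.5), rel=1e-9)

    def test_additivity_over_cells(self):
        cfg, U, T, truth = _toy()
        pl = pointwise_loglik(U, T, truth.items, truth.persons, cfg.pattern)
        g = cfg.pattern.group_of
        total = 0.0
        for i in range(cfg.N):
            for j in range(cfg.m):
                p = irt_prob(truth.items.d[j], truth.items.a_g[j],
                             truth.items.a_s[j], truth.persons.theta_g[i],
                             truth.persons.theta_s[i, g[j]])
                total += np.log(p if U[i, j] == 1 else 1 - p)
                total += log_rt_logdensity(
                    T[i, j], truth.items.beta[j], truth.items.alpha_g[j],
                    truth.items.alpha_s[j], truth.items.sigma[j],
                    truth.persons.tau_g[i], truth.persons.tau_s[i, g[j]])
        assert pl.total == pytest.approx(total, rel=1e-10)

    def test_reduction_chain_identities(self):
        """Zeroing the general loadings makes the full model's likelihood
        bit-identical to the no-general variant, and collapsing specifics
        reproduces the single-dimension variants."""
        cfg, U, T, truth = _toy()
        items0 = ItemParameters(
            a_g=np.zeros(cfg.m), a_s=truth.items.a_s, d=truth.items.d,
            alpha_g=np.zeros(cfg.m), alpha_s=truth.items.alpha_s,
            beta=truth.items.beta, sigma=truth.items.sigma)
        full = pointwise_loglik(U, T, items0, truth.persons, cfg.pattern,
                                ModelSpec(ModelVariant.BFHM))
        cmhm = pointwise_loglik(U, T, items0, truth.persons, cfg.pattern,
                                ModelSpec(ModelVariant.CMHM))
        np.testing.assert_array_equal(full.ra, cmhm.ra)
        np.testing.assert_array_equal(full.rt, cmhm.rt)

        # CMHM -> PMHM: with identical speed traits in every dimension the
        # collapsed RT side evaluates identically
        persons_flat = PersonParameters(
            theta_g=truth.persons.theta_g, theta_s=truth.persons.theta_s,
            tau_g=truth.persons.tau_g,
            tau_s=np.repeat(truth.persons.tau_s[:, :1], 3, axis=1))
        cmhm2 = pointwise_loglik(U, T, items0, persons_flat, cfg.pattern,
                                 ModelSpec(ModelVariant.CMHM))
        pmhm = pointwise_loglik(U, T, items0, persons_flat, cfg.pattern,
                                ModelSpec(ModelVariant.PMHM))
        np.testing.assert_array_equal(cmhm2.rt, pmhm.rt)

        # PMHM -> unidimensional: same collapse on the ability side
        persons_uni = PersonParameters(
            theta_g=truth.persons.theta_g,
            theta_s=np.repeat(truth.persons.theta_s[:, :1], 3, axis=1),
            tau_g=truth.persons.tau_g,
            tau_s=np.repeat(truth.persons.tau_s[:, :1], 3, axis=1))
        pmhm2 = pointwise_loglik(U, T, items0, persons_uni, cfg.pattern,
                                 ModelSpec(ModelVariant.PMHM))
        uni = pointwise_loglik(U, T, items0, persons_uni, cfg.pattern,
                               ModelSpec(ModelVariant.UNIDIM))
        np.testing.assert_array_equal(pmhm2.ra, uni.ra)
        np.testing.assert_array_equal(pmhm2.rt, uni.rt)

    def test_missing_cells_zero_and_counted(self):
        cfg, U, T, truth = _toy()
        U[0, 0] = np.nan
        T[1, 2] = np.nan
        T[3, 4] = np.nan
        pl = pointwise_loglik(U, T, truth.items, truth.persons, cfg.pattern)
        assert pl.ra[0, 0] == 0.0
        assert pl.rt[1, 2] == 0.0
        assert pl.n_missing_ra == 1
        assert pl.n_missing_rt == 2

    def test_item_permutation_invariance(self):
        cfg, U, T, truth = _toy()
        perm = np.random.default_rng(0).permutation(cfg.m)
        items_p = ItemParameters(
            a_g=truth.items.a_g[perm], a_s=truth.items.a_s[perm],
            d=truth.items.d[perm], alpha_g=truth.items.alpha_g[perm],
            alpha_s=truth.items.alpha_s[perm], beta=truth.items.beta[perm],
            sigma=truth.items.sigma[perm])
        pattern_p = LoadingPattern(cfg.m, 3, cfg.pattern.group_of[perm])
        pl = pointwise_loglik(U, T, truth.items, truth.persons, cfg.pattern)
        pl_p = pointwise_loglik(U[:, perm], T[:, perm], items_p,
                                truth.persons, pattern_p)
        assert pl_p.total == pytest.approx(pl.total, rel=1e-12)
        np.testing.assert_allclose(pl_p.ra, pl.ra[:, perm], rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        cfg, U, T, truth = _toy()
        with pytest.raises(ValueError):
            pointwise_loglik(U[:, :-1], T, truth.items, truth.persons,
                             cfg.pattern)

    def test_bad_values_rejected(self):
        cfg, U, T, truth = _toy()
        U2 = U.copy()
        U2[0, 0] = 2.0
        with pytest.raises(ValueError):
            pointwise_loglik(U2, T, truth.items, truth.persons, cfg.pattern)
        T2 = T.copy()
        T2[0, 0] = -1.0
        with pytest.raises(ValueError):
            pointwise_loglik(U, T2, truth.items, truth.persons, cfg.pattern)


class TestItemParameters:
    def test_positivity_enforced(self):
        m = 3
        ok = dict(a_g=np.ones(m), a_s=np.ones(m), d=np.zeros(m),
                  alpha_g=np.ones(m), alpha_s=np.ones(m), beta=np.full(m, 4.0),
                  sigma=np.ones(m))
        ItemParameters(**ok)
        for name in ("a_s", "alpha_s", "sigma"):
            bad = dict(ok)
            bad[name] = np.array([1.0, 0.0, 1.0])
            with pytest.raises(ValueError):
                ItemParameters(**bad)
        # general loadings may be exactly zero (reduced variants)
        ok2 = dict(ok)
        ok2["a_g"] = np.zeros(m)
        ItemParameters(**ok2)
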