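"""Generating-process checks: moments, orthogonality, determinism."""

import numpy as np
import pytest
from scipy import stats

from bfirt.models import irt_prob, log_rt_mean
from bfirt.simulate import (
    SimConfig,
    generate_item_params,
    generate_person_params,
    simulate_dataset,
)


class TestItemGeneration:
    def test_loadings_strictly_positive(self):
        cfg = SimConfig(N=10, m=300, n_specific=3, seed=1)
        items = generate_item_params(cfg)
        for arr in (items.a_g, items.a_s, items.alpha_g, items.alpha_s,
                    items.sigma):
            assert (arr > 0).all()

    def test_d_beta_moments(self):
        """Monte-Carlo moment check of the (d, beta) bivariate normal:
        means (0, 4), variances (1, 0.25), covariance -0.25."""
        m = 9999
        cfg = SimConfig(N=10, m=m, n_specific=3, seed=2)
        items = generate_item_params(cfg)
        se_d = 1.0 / np.sqrt(m)
        se_b = 0.5 / np.sqrt(m)
        assert abs(items.d.mean() - 0.0) < 3 * se_d
        assert abs(items.beta.mean() - 4.0) < 3 * se_b
        cov = np.cov(items.d, items.beta)
        assert cov[0, 0] == pytest.approx(1.0, abs=0.06)
        assert cov[1, 1] == pytest.approx(0.25, abs=0.02)
        assert cov[0, 1] == pytest.approx(-0.25, abs=0.03)

    def test_half_normal_loading_moments(self):
        m = 9999
        cfg = SimConfig(N=10, m=m, n_specific=3, seed=3)
        items = generate_item_params(cfg)
        expected_mean = np.sqrt(2 / np.pi)   # half-normal mean
        se = np.sqrt(1 - 2 / np.pi) / np.sqrt(m)
        for arr in (items.a_g, items.a_s, items.alpha_g, items.alpha_s):
            assert abs(arr.mean() - expected_mean) < 4 * se

    def test_seed_determinism(self):
        cfg = SimConfig(N=10, m=30, n_specific=3, seed=11)
        i1 = generate_item_params(cfg)
        i2 = generate_item_params(cfg)
        np.testing.assert_array_equal(i1.d, i2.d)
        np.testing.assert_array_equal(i1.sigma, i2.sigma)


class TestPersonGeneration:
    def test_empirical_correlation_matches_drawn(self):
        cfg = SimConfig(N=100_000, m=30, n_specific=3, seed=4)
        persons, structure = generate_person_params(cfg)
        r = np.corrcoef(persons.theta_g, persons.tau_g)[0, 1]
        assert r == pytest.approx(structure.rho_theta_g_tau_g, abs=0.01)
        for s in range(3):
            r_s = np.corrcoef(persons.theta_s[:, s], persons.tau_s[:, s])[0, 1]
            assert r_s == pytest.approx(structure.rho_theta_s_tau_s[s], abs=0.01)

    def test_cross_factor_orthogonality(self):
        cfg = SimConfig(N=100_000, m=30, n_specific=3, seed=5)
        persons, _ = generate_person_params(cfg)
        se = 1.0 / np.sqrt(cfg.N)
        assert abs(np.corrcoef(persons.theta_s[:, 0],
                               persons.theta_s[:, 1])[0, 1]) < 3 * se
        assert abs(np.corrcoef(persons.theta_g,
                               persons.theta_s[:, 2])[0, 1]) < 3 * se
        assert abs(np.corrcoef(persons.tau_s[:, 0],
                               persons.tau_s[:, 2])[0, 1]) < 3 * se

    def test_unit_marginal_variances(self):
        cfg = SimConfig(N=100_000, m=30, n_specific=3, seed=6)
        persons, _ = generate_person_params(cfg)
        se = np.sqrt(2.0 / cfg.N)   # SD of a chi^2-based variance estimate
        for arr in (persons.theta_g, persons.tau_g, persons.theta_s[:, 0],
                    persons.tau_s[:, 2]):
            assert abs(arr.var(ddof=1) - 1.0) < 3 * se

    def test_near_singular_correlation_warns(self):
        cfg = SimConfig(N=20, m=9, n_specific=3, seed=7, rho_general=0.995)
        with pytest.warns(RuntimeWarning, match="near-singular"):
            generate_person_params(cfg)

    def test_pinned_correlations(self):
        cfg = SimConfig(N=50, m=9, n_specific=3, seed=8, rho_general=-0.5,
                        rho_specific=(0.1, 0.2, 0.3))
        _, structure = generate_person_params(cfg)
        assert structure.rho_theta_g_tau_g == -0.5
        np.testing.assert_array_equal(structure.rho_theta_s_tau_s,
                                      [0.1, 0.2, 0.3])


class TestSimulateDataset:
    def test_outputs_well_formed(self):
        cfg = SimConfig(N=200, m=30, n_specific=3, seed=9)
        U, T, truth = simulate_dataset(cfg)
        assert U.shape == T.shape == (200, 30)
        assert set(np.unique(U)) <= {0, 1}
        assert (T > 0).all()

    def test_block_pattern_matches_design(self):
        cfg = SimConfig(N=5, m=30, n_specific=3, seed=9)
        S = cfg.pattern.indicator_matrix()
        expected = np.zeros((30, 3), dtype=int)
        expected[:10, 0] = expected[10:20, 1] = expected[20:, 2] = 1
        np.testing.assert_array_equal(S, expected)

    def test_accuracy_rates_match_model_probabilities(self):
        """Column means of the 0/1 matrix track the model probabilities
        (binomial Monte-Carlo check at N=50,000)."""
        cfg = SimConfig(N=50_000, m=9, n_specific=3, seed=10)
        U, T, truth = simulate_dataset(cfg)
        g = cfg.pattern.group_of
        P = irt_prob(truth.items.d[None, :], truth.items.a_g[None, :],
                     truth.items.a_s[None, :], truth.persons.theta_g[:, None],
                     truth.persons.theta_s[:, g])
        diff = U.mean(axis=0) - P.mean(axis=0)
        se = np.sqrt((P * (1 - P)).sum(axis=0)) / cfg.N
        assert (np.abs(diff) < 3.5 * se).all()

    def test_log_time_means_match_model(self):
        cfg = SimConfig(N=50_000, m=9, n_specific=3, seed=12)
        U, T, truth = simulate_dataset(cfg)
        g = cfg.pattern.group_of
        mu = log_rt_mean(truth.items.beta[None, :], truth.items.alpha_g[None, :],
                         truth.items.alpha_s[None, :],
                         truth.persons.tau_g[:, None], truth.persons.tau_s[:, g])
        diff = np.log(T).mean(axis=0) - mu.mean(axis=0)
        se = truth.items.sigma / np.sqrt(cfg.N)
        assert (np.abs(diff) < 3.5 * se).all()

    def test_standardized_log_time_residuals_normal(self):
        cfg = SimConfig(N=4000, m=9, n_specific=3, seed=13)
        U, T, truth = simulate_dataset(cfg)
        g = cfg.pattern.group_of
        mu = log_rt_mean(truth.items.beta[None, :], truth.items.alpha_g[None, :],
                         truth.items.alpha_s[None, :],
                         truth.persons.tau_g[:, None], truth.persons.tau_s[:, g])
        z = ((np.log(T) - mu) / truth.items.sigma[None, :]).ravel()
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_byte_identical_reproduction(self):
        cfg = SimConfig(N=100, m=30, n_specific=3, seed=14)
        U1, T1, tr1 = simulate_dataset(cfg)
        U2, T2, tr2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(U1, U2)
        np.testing.assert_array_equal(T1, T2)
        np.testing.assert_array_equal(tr1.persons.theta_s, tr2.persons.theta_s)

    def test_item_draws_stable_under_n_change(self):
        """Changing the number of examinees must not perturb item draws
        (independent substreams)."""
        i_small = simulate_dataset(SimConfig(N=20, m=30, seed=15))[2].items
        i_large = simulate_dataset(SimConfig(N=200, m=30, seed=15))[2].items
        np.testing.assert_array_equal(i_small.d, i_large.d)
        np.testing.assert_array_equal(i_small.beta, i_large.beta)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(N=0, m=30)
        with pytest.raises(ValueError):
            SimConfig(N=10, m=31, n_specific=3)   # not divisible
        with pytest.raises(ValueError):
            SimConfig(N=10, m=30, group_sizes=(10, 10))
        with pytest.raises(ValueError):
            SimConfig(N=10, m=30, var_d=1.0, var_beta=0.25, cov_d_beta=-0.9)
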