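import math

import numpy as np
import pytest
from scipy import stats

from gompertz_ssm.gompertz import (
    GompertzParams,
    LatentTrajectory,
    ThresholdBlock,
    obs_loglik,
    process_loglik,
    process_mean_linear,
    process_mean_threshold,
    simulate_pair,
)
from gompertz_ssm.timeseries_io import AnnualSeries

CAPELIN = GompertzParams(a0=5.74, a_self=0.56, a_cross=-0.49, a_st=0.17, a_nao=-0.01)
COD = GompertzParams(
    a0=0.94, a_self=0.84, a_cross=0.03, a_st=0.06, a_nao=0.05,
    threshold=ThresholdBlock(b0=-1.85, b_cross=0.52, theta=5.34),
)


class TestProcessMeans:
    def test_intercept_only(self):
        assert process_mean_linear(GompertzParams(a0=5.74), 0.0, 0.0) == 5.74

    def test_random_walk_identity(self):
        p = GompertzParams(a0=0.0, a_self=1.0)
        assert process_mean_linear(p, 3.2, 99.0) == 3.2

    def test_linear_reference_values(self):
        # hand arithmetic: 5.74 + 0.56*5 - 0.49*6 + 0.17*1 - 0.01*(-1)
        assert process_mean_linear(CAPELIN, 5.0, 6.0, 1.0, -1.0) == pytest.approx(5.78)

    def test_threshold_lower_and_upper(self):
        # lower regime: 0.94 + 0.84*7 + 0.03*5
        assert process_mean_threshold(COD, 7.0, 5.0) == pytest.approx(6.97)
        # upper regime: -1.85 + 0.84*7 + 0.52*6
        assert process_mean_threshold(COD, 7.0, 6.0) == pytest.approx(7.15)

    def test_boundary_is_upper_regime(self):
        at_theta = process_mean_threshold(COD, 7.0, 5.34)
        upper = COD.threshold.b0 + COD.a_self * 7.0 + COD.threshold.b_cross * 5.34
        assert at_theta == pytest.approx(upper)

    def test_regime_collapse_identity(self):
        collapsed = COD.collapse_threshold()
        rng = np.random.default_rng(0)
        for _ in range(50):
            args = rng.normal(5, 2, 4)
            assert process_mean_threshold(collapsed, *args) == pytest.approx(
                process_mean_linear(collapsed, *args), abs=1e-12
            )

    def test_threshold_requires_block(self):
        with pytest.raises(ValueError):
            process_mean_threshold(CAPELIN, 5.0, 5.0)


def _random_toy(rng, T):
    years = np.arange(2000, 2000 + T)
    p = GompertzParams(
        a0=rng.normal(1, 1),
        a_self=rng.uniform(0.2, 0.9),
        a_cross=rng.normal(0, 0.4),
        a_st=rng.normal(0, 0.2),
        a_nao=rng.normal(0, 0.2),
        sigma_proc=rng.uniform(0.1, 0.6),
        sigma_obs=rng.uniform(0.1, 0.6),
        threshold=ThresholdBlock(
            b0=rng.normal(0, 1), b_cross=rng.normal(0, 0.5), theta=rng.normal(5, 0.5)
        )
        if rng.random() < 0.5
        else None,
    )
    self_t = LatentTrajectory(years=years, ln_n=rng.normal(5, 1, T))
    part_t = LatentTrajectory(years=years, ln_n=rng.normal(5, 1, T))
    st = rng.standard_normal(T)
    nao = rng.standard_normal(T)
    return p, self_t, part_t, st, nao


class TestLogLikelihoods:
    def test_matches_brute_force_on_random_toys(self):
        """process/obs log-likelihoods equal independent per-year
        Gaussian sums over 100 random 5-10 year toys."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            T = int(rng.integers(5, 11))
            p, self_t, part_t, st, nao = _random_toy(rng, T)
            ll = process_loglik(p, self_t, part_t, st, nao, partner_lag=1)
            expected = 0.0
            for t in range(1, T):
                prev_self = self_t.ln_n[t - 1]
                part = part_t.ln_n[t - 1]
                if p.threshold is not None and part >= p.threshold.theta:
                    mu = (
                        p.threshold.b0 + p.a_self * prev_self
                        + p.threshold.b_cross * part
                        + p.a_st * st[t - 1] + p.a_nao * nao[t - 1]
                    )
                else:
                    mu = (
                        p.a0 + p.a_self * prev_self + p.a_cross * part
                        + p.a_st * st[t - 1] + p.a_nao * nao[t - 1]
                    )
                expected += stats.norm.logpdf(self_t.ln_n[t], mu, p.sigma_proc)
            assert ll == pytest.approx(expected, abs=1e-10)

            obs = AnnualSeries(
                years=self_t.years,
                values=np.exp(self_t.ln_n + rng.normal(0, 0.2, T)),
            )
            ol = obs_loglik(p, self_t, obs)
            expected_obs = float(
                np.sum(stats.norm.logpdf(np.log(obs.values), self_t.ln_n, p.sigma_obs))
            )
            assert ol == pytest.approx(expected_obs, abs=1e-10)

    def test_zero_residual_closed_form(self):
        rng = np.random.default_rng(1)
        p, self_t, part_t, st, nao = _random_toy(rng, 6)
        # build a trajectory exactly at the process means
        ln_n = np.empty(6)
        ln_n[0] = self_t.ln_n[0]
        for t in range(1, 6):
            part = part_t.ln_n[t - 1]
            if p.threshold is not None and part >= p.threshold.theta:
                mu = (p.threshold.b0 + p.a_self * ln_n[t - 1]
                      + p.threshold.b_cross * part + p.a_st * st[t - 1]
                      + p.a_nao * nao[t - 1])
            else:
                mu = (p.a0 + p.a_self * ln_n[t - 1] + p.a_cross * part
                      + p.a_st * st[t - 1] + p.a_nao * nao[t - 1])
            ln_n[t] = mu
        traj = LatentTrajectory(years=self_t.years, ln_n=ln_n)
        ll = process_loglik(p, traj, part_t, st, nao, partner_lag=1)
        assert ll == pytest.approx(
            5 * (-0.5 * math.log(2 * math.pi * p.sigma_proc**2)), abs=1e-10
        )
        # doubling sigma with zero residuals lowers loglik by T ln 2
        import dataclasses

        p2 = dataclasses.replace(p, sigma_proc=2 * p.sigma_proc)
        assert process_loglik(p2, traj, part_t, st, nao, partner_lag=1) == pytest.approx(
            ll - 5 * math.log(2), abs=1e-10
        )

    def test_obs_quadratic_identity(self):
        years = np.arange(2000, 2006)
        ln_n = np.full(6, 5.0)
        traj = LatentTrajectory(years=years, ln_n=ln_n)
        p = GompertzParams(sigma_obs=0.4)
        obs0 = AnnualSeries(years=years, values=np.exp(ln_n))
        base = obs_loglik(p, traj, obs0)
        c = 0.37
        shifted = np.exp(ln_n.copy())
        shifted[2] = np.exp(ln_n[2] + c)
        obs1 = AnnualSeries(years=years, values=shifted)
        assert obs_loglik(p, traj, obs1) - base == pytest.approx(
            -(c**2) / (2 * p.sigma_obs**2), abs=1e-10
        )

    def test_zero_process_sd_sentinel(self):
        years = np.arange(2000, 2005)
        traj = LatentTrajectory(years=years, ln_n=np.array([1.0, 5.0, 1.0, 5.0, 1.0]))
        part = LatentTrajectory(years=years, ln_n=np.zeros(5))
        p = GompertzParams(a_self=1.0, sigma_proc=0.0)
        assert process_loglik(p, traj, part, partner_lag=1) == -math.inf


class TestSimulatePair:
    def test_reproducible_and_seed_sensitive(self):
        import dataclasses

        cod = dataclasses.replace(COD, sigma_proc=0.3, sigma_obs=0.3)
        cap = dataclasses.replace(CAPELIN, sigma_proc=0.3, sigma_obs=0.3)
        out1 = simulate_pair(cod, cap, (6.7, 5.6), n_years=20, seed=9)
        out2 = simulate_pair(cod, cap, (6.7, 5.6), n_years=20, seed=9)
        out3 = simulate_pair(cod, cap, (6.7, 5.6), n_years=20, seed=10)
        assert np.array_equal(out1[0].ln_n, out2[0].ln_n)
        assert np.array_equal(out1[3].values, out2[3].values)
        assert not np.array_equal(out1[0].ln_n, out3[0].ln_n)

    def test_noise_free_equals_deterministic_recursion(self):
        import dataclasses

        cod0 = dataclasses.replace(COD, sigma_proc=0.0, sigma_obs=0.0)
        cap0 = dataclasses.replace(CAPELIN, sigma_proc=0.0, sigma_obs=0.0)
        lat_u, lat_v, obs_u, obs_v = simulate_pair(cod0, cap0, (6.7, 5.6), n_years=15, seed=1)
        u, v = 6.7, 5.6
        for t in range(1, 15):
            u_new = process_mean_threshold(cod0, u, v)
            v_new = process_mean_linear(cap0, v, u_new)
            u, v = u_new, v_new
            assert lat_u.ln_n[t] == pytest.approx(u, abs=1e-12)
            assert lat_v.ln_n[t] == pytest.approx(v, abs=1e-12)
        assert np.allclose(np.log(obs_u.values), lat_u.ln_n)

    def test_noise_free_regime_crossing_at_theta(self):
        """The noise-free predator switches regimes exactly when lagged
        prey log abundance crosses theta (boundary in the upper regime)."""
        import dataclasses

        cod0 = dataclasses.replace(COD, sigma_proc=0.0, sigma_obs=0.0)
        for v_prev in (5.3399, 5.34, 5.3401):
            mu = process_mean_threshold(cod0, 6.0, v_prev)
            lower = cod0.a0 + cod0.a_self * 6.0 + cod0.a_cross * v_prev
            upper = (cod0.threshold.b0 + cod0.a_self * 6.0
                     + cod0.threshold.b_cross * v_prev)
            assert mu == (lower if v_prev < 5.34 else upper)

    def test_single_species_stationary_moments(self):
        """AR(1) limit: mean a0/(1-a_self), variance sigma^2/(1-a_self^2)."""
        p = GompertzParams(a0=1.0, a_self=0.5, sigma_proc=0.3)
        other = GompertzParams(a0=0.0, a_self=0.0, sigma_proc=0.0)
        lat, _, _, _ = simulate_pair(p, other, (2.0, 0.0), n_years=20000, seed=5)
        x = lat.ln_n[100:]
        assert np.mean(x) == pytest.approx(2.0, abs=0.02)
        assert np.var(x) == pytest.approx(0.09 / (1 - 0.25), rel=0.1)

    def test_cyclic_lag_rejected(self):
        from gompertz_ssm.timeseries_io import LagConvention

        with pytest.raises(ValueError, match="cycle"):
            simulate_pair(
                COD, CAPELIN, (6.7, 5.6), n_years=10, seed=1,
                lag=LagConvention(predator_prey_lag=0, prey_predator_lag=0),
            )

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_pair(COD, CAPELIN, (6.7, 5.6), n_years=10)
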