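"""Oracle checks of the state-space kernels against dense linear algebra.

The coupled model is linear-Gaussian conditional on a regime sequence,
so every kernel (marginal likelihood, smoother draws, conditional
species draws, single-site sweeps) can be verified against the joint
multivariate normal assembled explicitly for a short series.
"""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gompertz_ssm import _kalman

T = 6
PSY = True  # prey uses the predator's same-year state


def _transition_mats(t, rp, rq, cp, cq, sig, st, nao):
    out = _kalman._transition.py_func(t, rp, rq, cp, cq, sig, st, nao, PSY)
    cu, c2, a11, a12, a21, a22, q11, q12, q22 = out
    A = np.array([[a11, a12], [a21, a22]])
    c = np.array([cu, c2])
    Q = np.array([[q11, q12], [q12, q22]])
    return c, A, Q


def _joint_gaussian(y, st, nao, rp, rq, cp, cq, sig, m0, s0):
    """Mean and covariance of the stacked latent states and the implied
    observation distribution, by explicit linear propagation."""
    d = 2 * T
    mu = np.zeros(d)
    M = np.zeros((d, d))
    Sxi = np.zeros((d, d))
    mu[:2] = m0
    M[:2, :2] = np.eye(2)
    Sxi[0, 0], Sxi[1, 1] = s0[0] ** 2, s0[1] ** 2
    for t in range(1, T):
        c, A, Q = _transition_mats(t, rp, rq, cp, cq, sig, st, nao)
        mu[2 * t : 2 * t + 2] = c + A @ mu[2 * (t - 1) : 2 * t]
        M[2 * t : 2 * t + 2, :] = A @ M[2 * (t - 1) : 2 * t, :]
        M[2 * t : 2 * t + 2, 2 * t : 2 * t + 2] = np.eye(2)
        Sxi[2 * t : 2 * t + 2, 2 * t : 2 * t + 2] = Q
    Sx = M @ Sxi @ M.T
    R = np.diag([sig[1] ** 2, sig[3] ** 2] * T)
    return mu, Sx, Sx + R


@pytest.fixture()
def random_system():
    rng = np.random.default_rng(17)

    def make(threshold=True):
        cp = np.array([0.9, 0.8, 0.05, 0.06, 0.05, -1.8, 0.5])
        cq = np.array([5.7, 0.55, -0.5, 0.17, -0.01, 0.0, 0.0])
        cq[5], cq[6] = cq[0], cq[2]
        cp = cp + 0.1 * rng.standard_normal(7)
        sig = np.abs(rng.normal(0.3, 0.1, 4)) + 0.05
        st, nao = rng.standard_normal((2, T))
        rp = (rng.random(T) < 0.5).astype(np.int64) if threshold else np.zeros(T, np.int64)
        rp[0] = 0
        rq = np.zeros(T, dtype=np.int64)
        y = rng.normal(5, 1, (T, 2))
        m0, s0 = y[0].copy(), np.array([1.0, 1.0])
        return y, st, nao, rp, rq, cp, cq, sig, m0, s0

    return make


class TestKalmanFilter:
    def test_marginal_loglik_matches_dense_gaussian(self, random_system):
        for _ in range(20):
            args = random_system()
            y = args[0]
            ll, _, _ = _kalman.kalman_filter(*args, PSY)
            mu, _, Sy = _joint_gaussian(*args)
            expected = multivariate_normal.logpdf(y.reshape(-1), mu, Sy)
            assert ll == pytest.approx(expected, abs=1e-10)

    def test_process_loglik_latent_matches_direct_sum(self, random_system):
        rng = np.random.default_rng(3)
        y, st, nao, rp, rq, cp, cq, sig, m0, s0 = random_system()
        x = rng.normal(5, 1, (T, 2))
        got = _kalman.process_loglik_latent(x, st, nao, rp, rq, cp, cq, sig, PSY)
        expected = 0.0
        from scipy.stats import norm

        for t in range(1, T):
            a0u, acu = (cp[0], cp[2]) if rp[t] == 0 else (cp[5], cp[6])
            mu_u = a0u + cp[1] * x[t - 1, 0] + acu * x[t - 1, 1] + cp[3] * st[t - 1] + cp[4] * nao[t - 1]
            expected += norm.logpdf(x[t, 0], mu_u, sig[0])
            mu_v = cq[0] + cq[1] * x[t - 1, 1] + cq[2] * x[t, 0] + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
            expected += norm.logpdf(x[t, 1], mu_v, sig[2])
        assert got == pytest.approx(expected, abs=1e-10)


def _conditional_moments(mu, Sx, Sy, y, sig):
    K = Sx @ np.linalg.inv(Sy)
    cm = mu + K @ (y.reshape(-1) - mu)
    cc = Sx - K @ Sx
    return cm, cc


class TestSmootherDraws:
    def test_ffbs_moments(self, random_system):
        args = random_system()
        y, st, nao, rp, rq, cp, cq, sig, m0, s0 = args
        _, mf, Pf = _kalman.kalman_filter(*args, PSY)
        mu, Sx, Sy = _joint_gaussian(*args)
        cm, cc = _conditional_moments(mu, Sx, Sy, y, sig)
        rng = np.random.default_rng(0)
        n = 20000
        draws = np.empty((n, 2 * T))
        for i in range(n):
            x, _ = _kalman.ffbs(mf, Pf, st, nao, rp, rq, cp, cq, sig, PSY,
                                rng.standard_normal((T, 2)))
            draws[i] = x.reshape(-1)
        assert np.abs(draws.mean(0) - cm).max() < 0.02
        assert np.abs(np.cov(draws.T) - cc).max() < 0.01

    def test_species_conditional_draws_and_sweep_invariance(self, random_system):
        """predator FFBS, conditional prey FFBS (full and windowed) and
        the single-site sweep all preserve / sample the exact species
        conditionals, checked via dense conditional Gaussians."""
        args = random_system(threshold=False)
        y, st, nao, rp, rq, cp, cq, sig, m0, s0 = args
        rng = np.random.default_rng(1)
        u = rng.normal(6, 0.5, T)
        v0 = rng.normal(5.5, 0.5, T)

        # dense conditional of v | u, y_v
        acc, acv = cq[1], cq[2]
        muv = np.zeros(T)
        Mv = np.zeros((T, T))
        Sv_in = np.zeros((T, T))
        muv[0] = m0[1]
        Mv[0, 0] = 1.0
        Sv_in[0, 0] = s0[1] ** 2
        for t in range(1, T):
            cvt = cq[0] + acv * u[t] + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
            muv[t] = cvt + acc * muv[t - 1]
            Mv[t] = acc * Mv[t - 1]
            Mv[t, t] = 1.0
            Sv_in[t, t] = sig[2] ** 2
        Sv = Mv @ Sv_in @ Mv.T
        H2 = np.zeros((T - 1, T))
        r2 = np.zeros(T - 1)
        for t in range(T - 1):
            H2[t, t] = cp[2]
            r2[t] = u[t + 1] - (cp[0] + cp[1] * u[t] + cp[3] * st[t] + cp[4] * nao[t])
        H = np.vstack([np.eye(T), H2])
        robs = np.concatenate([y[:, 1], r2])
        R = np.diag(np.concatenate([np.full(T, sig[3] ** 2), np.full(T - 1, sig[0] ** 2)]))
        S = H @ Sv @ H.T + R
        K = Sv @ H.T @ np.linalg.inv(S)
        cm = muv + K @ (robs - H @ muv)
        cc = Sv - K @ H @ Sv

        n = 15000
        d_full = np.empty((n, T))
        d_win = np.empty((n, T))
        d_sweep = np.empty((n, T))
        for i in range(n):
            out, _ = _kalman.prey_window_ffbs(
                y[:, 1], u, st, nao, rp, cp, cq, sig, m0[1], s0[1], PSY,
                rng.standard_normal(T), 0, T - 1, v0,
            )
            d_full[i] = out
            # windowed redraw applied to halves, starting from an exact draw
            vv = out.copy()
            for s_w, e_w in ((0, 2), (3, T - 1)):
                w, _ = _kalman.prey_window_ffbs(
                    y[:, 1], u, st, nao, rp, cp, cq, sig, m0[1], s0[1], PSY,
                    rng.standard_normal(e_w - s_w + 1), s_w, e_w, vv,
                )
                vv[s_w : e_w + 1] = w
            d_win[i] = vv
            vv2 = out.copy()
            _kalman.prey_gibbs_sweep(
                vv2, u, y[:, 1], st, nao, cp, cq, sig, 0.0, False,
                m0[1], s0[1], PSY, rng.random((T, 2)), False,
            )
            d_sweep[i] = vv2
        for d in (d_full, d_win, d_sweep):
            assert np.abs(d.mean(0) - cm).max() < 0.03
            assert np.abs(np.cov(d.T) - cc).max() < 0.01

    def test_prey_invert_roundtrip(self, random_system):
        y, st, nao, rp, rq, cp, cq, sig, m0, s0 = random_system()
        rng = np.random.default_rng(2)
        u = rng.normal(6, 0.5, T)
        eps0 = rng.standard_normal(T)
        v, ll1 = _kalman.prey_window_ffbs(
            y[:, 1], u, st, nao, rp, cp, cq, sig, m0[1], s0[1], PSY,
            eps0, 0, T - 1, np.zeros(T),
        )
        eps, ll2 = _kalman.prey_ffbs_invert(
            y[:, 1], u, st, nao, rp, cp, cq, sig, m0[1], s0[1], PSY, v
        )
        assert np.allclose(eps, eps0, atol=1e-9)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_innovation_bijection(self, random_system):
        y, st, nao, rp, rq, cp, cq, sig, m0, s0 = random_system()
        rng = np.random.default_rng(4)
        x = rng.normal(5, 1, (T, 2))
        eta = _kalman.eta_from_x(x, st, nao, cp, cq, sig, 5.34, True, 0.0, False, PSY)
        back = _kalman.x_from_eta(
            x[0, 0], x[0, 1], eta, st, nao, cp, cq, sig, 5.34, True, 0.0, False, PSY
        )
        assert np.allclose(back, x, atol=1e-10)


class TestNdtri:
    def test_matches_scipy(self):
        from scipy.special import ndtri

        ps = np.concatenate([[1e-12, 1e-6], np.linspace(0.001, 0.999, 51), [1 - 1e-9]])
        ours = np.array([_kalman._ndtri(p) for p in ps])
        assert np.allclose(ours, ndtri(ps), atol=1e-9)
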