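"""Kalman filtering and backward sampling for the coupled two-species model.

Conditional on a fixed regime sequence for each species' transition, the
coupled threshold Gompertz model is linear-Gaussian in the joint latent
state ``x_t = (ln N_pred, ln N_prey)``.  When the prey equation uses the
predator's same-year state, substituting the predator equation into the
prey equation gives a standard first-order transition

    x_t = c_t + A_t x_{t-1} + w_t,   w_t ~ N(0, Q_t),

with correlated innovations (the predator's process shock propagates
into the prey within the year).  These kernels provide the exact
marginal log-likelihood (Kalman filter), forward-filter backward-sampling
of latent trajectories with the proposal's log-density, and the exact
process log-density given a latent trajectory.

Coefficient packing per species: ``[a0, a_self, a_cross, a_st, a_nao,
b0, b_cross]`` (linear species simply carry ``b0=a0, b_cross=a_cross``).
``sig = [sig_proc_pred, sig_obs_pred, sig_proc_prey, sig_obs_prey]``.
Regime arrays hold, per year t, the regime (0 lower / 1 upper) of the
transition *into* year t; index 0 is unused.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _transition(t, rp, rq, cp, cq, sig, st, nao, prey_same_year):
    """Build (c, A, Q) of the joint transition into year t (t >= 1)."""
    if rp[t] == 0:
        a0u, acu = cp[0], cp[2]
    else:
        a0u, acu = cp[5], cp[6]
    cu = a0u + cp[3] * st[t - 1] + cp[4] * nao[t - 1]
    a11 = cp[1]
    a12 = acu
    if rq[t] == 0:
        a0v, acv = cq[0], cq[2]
    else:
        a0v, acv = cq[5], cq[6]
    cv = a0v + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
    qu = sig[0] * sig[0]
    qv = sig[2] * sig[2]
    if prey_same_year:
        c2 = cv + acv * cu
        a21 = acv * a11
        a22 = cq[1] + acv * a12
        q11 = qu
        q12 = acv * qu
        q22 = acv * acv * qu + qv
    else:
        c2 = cv
        a21 = acv
        a22 = cq[1]
        q11 = qu
        q12 = 0.0
        q22 = qv
    return cu, c2, a11, a12, a21, a22, q11, q12, q22


@njit(cache=True)
def kalman_filter(y, st, nao, rp, rq, cp, cq, sig, m0, s0, prey_same_year):
    """Marginal log-likelihood of observed log abundances, plus the
    filtered means/covariances needed for backward sampling.

    Returns ``(loglik, mf, Pf)`` with ``mf`` of shape (T, 2) and ``Pf``
    of shape (T, 3) packing the symmetric covariance (P11, P12, P22).
    """
    T = y.shape[0]
    ro_u = sig[1] * sig[1]
    ro_v = sig[3] * sig[3]
    mf = np.empty((T, 2))
    Pf = np.empty((T, 3))
    ll = 0.0

    m1, m2 = m0[0], m0[1]
    p11, p12, p22 = s0[0] * s0[0], 0.0, s0[1] * s0[1]
    for t in range(T):
        if t > 0:
            cu, c2, a11, a12, a21, a22, q11, q12, q22 = _transition(
                t, rp, rq, cp, cq, sig, st, nao, prey_same_year
            )
            nm1 = cu + a11 * m1 + a12 * m2
            nm2 = c2 + a21 * m1 + a22 * m2
            # A P A' + Q for symmetric P
            t11 = a11 * p11 + a12 * p12
            t12 = a11 * p12 + a12 * p22
            t21 = a21 * p11 + a22 * p12
            t22 = a21 * p12 + a22 * p22
            p11 = t11 * a11 + t12 * a12 + q11
            p12 = t11 * a21 + t12 * a22 + q12
            p22 = t21 * a21 + t22 * a22 + q22
            m1, m2 = nm1, nm2
        # observation update with R = diag(ro_u, ro_v)
        s11 = p11 + ro_u
        s12 = p12
        s22 = p22 + ro_v
        det = s11 * s22 - s12 * s12
        if det <= 0.0:
            return -np.inf, mf, Pf
        i11 = s22 / det
        i12 = -s12 / det
        i22 = s11 / det
        e1 = y[t, 0] - m1
        e2 = y[t, 1] - m2
        maha = e1 * (i11 * e1 + i12 * e2) + e2 * (i12 * e1 + i22 * e2)
        ll += -0.5 * (2.0 * _LOG_2PI + math.log(det) + maha)
        # K = P S^{-1}
        k11 = p11 * i11 + p12 * i12
        k12 = p11 * i12 + p12 * i22
        k21 = p12 * i11 + p22 * i12
        k22 = p12 * i12 + p22 * i22
        m1 = m1 + k11 * e1 + k12 * e2
        m2 = m2 + k21 * e1 + k22 * e2
        # P - K P (with K = P S^{-1}, S = P + R, this stays symmetric)
        np11 = p11 - (k11 * p11 + k12 * p12)
        np12 = p12 - (k11 * p12 + k12 * p22)
        np22 = p22 - (k21 * p12 + k22 * p22)
        p11, p12, p22 = np11, np12, np22
        mf[t, 0], mf[t, 1] = m1, m2
        Pf[t, 0], Pf[t, 1], Pf[t, 2] = p11, p12, p22
    return ll, mf, Pf


@njit(cache=True)
def _sample2(m1, m2, p11, p12, p22, e1, e2):
    """Draw from N((m1, m2), P) using standard-normal inputs (e1, e2);
    returns the draw and its log-density."""
    j = 1e-12
    l11 = math.sqrt(max(p11 + j, 1e-300))
    l21 = p12 / l11
    l22 = math.sqrt(max(p22 + j - l21 * l21, 1e-300))
    x1 = m1 + l11 * e1
    x2 = m2 + l21 * e1 + l22 * e2
    logpdf = -_LOG_2PI - math.log(l11 * l22) - 0.5 * (e1 * e1 + e2 * e2)
    return x1, x2, logpdf


@njit(cache=True)
def ffbs(mf, Pf, st, nao, rp, rq, cp, cq, sig, prey_same_year, eps):
    """Backward-sample a latent trajectory from the filtered quantities.

    ``eps`` is a (T, 2) array of standard normals consumed
    deterministically, making the draw reproducible from the caller's
    RNG.  Returns the trajectory (T, 2) and its exact log-density under
    the conditionally linear-Gaussian model (the FFBS proposal density).
    """
    T = mf.shape[0]
    x = np.empty((T, 2))
    logq = 0.0
    x1, x2, lp = _sample2(
        mf[T - 1, 0], mf[T - 1, 1], Pf[T - 1, 0], Pf[T - 1, 1], Pf[T - 1, 2],
        eps[T - 1, 0], eps[T - 1, 1],
    )
    x[T - 1, 0], x[T - 1, 1] = x1, x2
    logq += lp
    for t in range(T - 2, -1, -1):
        cu, c2, a11, a12, a21, a22, q11, q12, q22 = _transition(
            t + 1, rp, rq, cp, cq, sig, st, nao, prey_same_year
        )
        p11, p12, p22 = Pf[t, 0], Pf[t, 1], Pf[t, 2]
        m1, m2 = mf[t, 0], mf[t, 1]
        # predictive of x_{t+1} given filtration at t
        mp1 = cu + a11 * m1 + a12 * m2
        mp2 = c2 + a21 * m1 + a22 * m2
        t11 = a11 * p11 + a12 * p12
        t12 = a11 * p12 + a12 * p22
        t21 = a21 * p11 + a22 * p12
        t22 = a21 * p12 + a22 * p22
        pp11 = t11 * a11 + t12 * a12 + q11
        pp12 = t11 * a21 + t12 * a22 + q12
        pp22 = t21 * a21 + t22 * a22 + q22
        det = pp11 * pp22 - pp12 * pp12
        if det <= 1e-300:
            det = 1e-300
        i11 = pp22 / det
        i12 = -pp12 / det
        i22 = pp11 / det
        # C = Cov(x_t, x_{t+1}) = P A'; J = C Pp^{-1}
        c11 = p11 * a11 + p12 * a12
        c12 = p11 * a21 + p12 * a22
        c21 = p12 * a11 + p22 * a12
        c22 = p12 * a21 + p22 * a22
        j11 = c11 * i11 + c12 * i12
        j12 = c11 * i12 + c12 * i22
        j21 = c21 * i11 + c22 * i12
        j22 = c21 * i12 + c22 * i22
        e1 = x[t + 1, 0] - mp1
        e2 = x[t + 1, 1] - mp2
        cm1 = m1 + j11 * e1 + j12 * e2
        cm2 = m2 + j21 * e1 + j22 * e2
        # conditional covariance P - J C'
        cv11 = p11 - (j11 * c11 + j12 * c12)
        cv12 = p12 - (j11 * c21 + j12 * c22)
        cv22 = p22 - (j21 * c21 + j22 * c22)
        x1, x2, lp = _sample2(cm1, cm2, cv11, cv12, cv22, eps[t, 0], eps[t, 1])
        x[t, 0], x[t, 1] = x1, x2
        logq += lp
    return x, logq


@njit(cache=True)
def process_loglik_latent(x, st, nao, rp, rq, cp, cq, sig, prey_same_year):
    """Exact process log-density of a latent trajectory given regimes."""
    T = x.shape[0]
    sp_u, sp_v = sig[0], sig[2]
    ll = 0.0
    for t in range(1, T):
        if rp[t] == 0:
            a0u, acu = cp[0], cp[2]
        else:
            a0u, acu = cp[5], cp[6]
        mu_u = (
            a0u
            + cp[1] * x[t - 1, 0]
            + acu * x[t - 1, 1]
            + cp[3] * st[t - 1]
            + cp[4] * nao[t - 1]
        )
        eu = x[t, 0] - mu_u
        ll += -0.5 * (_LOG_2PI + 2.0 * math.log(sp_u) + (eu / sp_u) ** 2)
        if rq[t] == 0:
            a0v, acv = cq[0], cq[2]
        else:
            a0v, acv = cq[5], cq[6]
        partner = x[t, 0] if prey_same_year else x[t - 1, 0]
        mu_v = (
            a0v
            + cq[1] * x[t - 1, 1]
            + acv * partner
            + cq[3] * st[t - 1]
            + cq[4] * nao[t - 1]
        )
        ev = x[t, 1] - mu_v
        ll += -0.5 * (_LOG_2PI + 2.0 * math.log(sp_v) + (ev / sp_v) ** 2)
    return ll


def regimes_from_series(
    pred_vals: np.ndarray,
    prey_vals: np.ndarray,
    theta_pred: float | None,
    theta_prey: float | None,
    prey_same_year: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Regime indicator arrays from log-abundance series.

    The predator's transition into year t is in the upper regime when
    the prey's value at t-1 is at or above ``theta_pred``; the prey's
    regime (only when the prey is threshold-typed) uses the predator at
    t (same-year convention) or t-1.  ``None`` thresholds give all-lower
    (linear) regimes.
    """
    T = len(pred_vals)
    rp = np.zeros(T, dtype=np.int64)
    rq = np.zeros(T, dtype=np.int64)
    if theta_pred is not None:
        rp[1:] = (prey_vals[:-1] >= theta_pred).astype(np.int64)
    if theta_prey is not None:
        src = pred_vals[1:] if prey_same_year else pred_vals[:-1]
        rq[1:] = (src >= theta_prey).astype(np.int64)
    return rp, rq


# -- species-conditional exact Gibbs kernels ----------------------------
#
# With the prey path fixed, the predator chain is linear-Gaussian (its
# regimes are determined), and each prey transition is a linear
# observation of the predator state, so the predator path has an exact
# scalar FFBS draw.  Conversely each prey state's full conditional given
# everything else is piecewise Gaussian: the only non-Gaussian factor is
# the next year's predator transition, whose regime switches at theta,
# giving a two-branch truncated-Gaussian mixture that is sampled exactly.


@njit(cache=True)
def _ndtri(p):
    """Inverse standard normal CDF (Acklam's rational approximation,
    refined with one Halley step; ~1e-12 absolute error)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / (
            (((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0
        )
    elif p <= 1.0 - plow:
        q = p - 0.5
        r = q * q
        x = (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / (
            ((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0
        )
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / (
            (((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0
        )
    # one Halley refinement
    e = 0.5 * math.erfc(-x / math.sqrt(2.0)) - p
    u = e * math.sqrt(2.0 * math.pi) * math.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True)
def _phi(z):
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


@njit(cache=True)
def predator_ffbs(y_u, v, st, nao, rp, cp, cq, sig, m0u, s0u, prey_same_year, eps):
    """Exact draw of the predator latent path given the prey path.

    Scalar Kalman filter over u with two observation streams: the
    predator survey (sd sigma_obs_pred) and, through the prey process
    equation, each prey transition (a linear observation of u with
    coefficient a_prey_pred and sd sigma_proc_prey); then backward
    sampling.  ``eps`` supplies T standard normals.  Returns the draw
    and the stream marginal log-likelihood (the evidence of all
    u-attached factors given the prey path), which makes exact marginal
    variance moves possible on the predator block.
    """
    T = y_u.shape[0]
    sp_u, so_u, sp_v = sig[0], sig[1], sig[2]
    acc_v = cq[1]
    acv = cq[2]  # prey's predator coefficient (prey assumed linear)
    mf = np.empty(T)
    pf = np.empty(T)
    ll = 0.0
    m = m0u
    p = s0u * s0u
    for t in range(T):
        if t > 0:
            if rp[t] == 0:
                a0u, acu = cp[0], cp[2]
            else:
                a0u, acu = cp[5], cp[6]
            cu = a0u + acu * v[t - 1] + cp[3] * st[t - 1] + cp[4] * nao[t - 1]
            m = cu + cp[1] * m
            p = cp[1] * cp[1] * p + sp_u * sp_u
        # survey observation of u_t
        s = p + so_u * so_u
        ll += -0.5 * (_LOG_2PI + math.log(s) + (y_u[t] - m) ** 2 / s)
        k = p / s
        m = m + k * (y_u[t] - m)
        p = p * (1.0 - k)
        # prey-transition observation of u_t
        if prey_same_year:
            has_obs = t >= 1
            tt = t
        else:
            has_obs = t <= T - 2
            tt = t + 1
        if has_obs and acv != 0.0:
            cv = cq[0] + acc_v * v[tt - 1] + cq[3] * st[tt - 1] + cq[4] * nao[tt - 1]
            r = v[tt] - cv
            s = acv * acv * p + sp_v * sp_v
            ll += -0.5 * (_LOG_2PI + math.log(s) + (r - acv * m) ** 2 / s)
            k = p * acv / s
            m = m + k * (r - acv * m)
            p = p * (1.0 - k * acv)
        mf[t] = m
        pf[t] = p
    u = np.empty(T)
    u[T - 1] = mf[T - 1] + math.sqrt(max(pf[T - 1], 0.0)) * eps[T - 1]
    for t in range(T - 2, -1, -1):
        if rp[t + 1] == 0:
            a0u, acu = cp[0], cp[2]
        else:
            a0u, acu = cp[5], cp[6]
        cu = a0u + acu * v[t] + cp[3] * st[t] + cp[4] * nao[t]
        pp = cp[1] * cp[1] * pf[t] + sp_u * sp_u
        j = pf[t] * cp[1] / pp
        mean = mf[t] + j * (u[t + 1] - (cu + cp[1] * mf[t]))
        var = pf[t] - j * j * pp
        u[t] = mean + math.sqrt(max(var, 0.0)) * eps[t]
    return u, ll


@njit(cache=True)
def prey_gibbs_sweep(
    v, u, y_v, st, nao, cp, cq, sig, theta, has_threshold,
    m0v, s0v, prey_same_year, u01, backward,
):
    """One systematic sweep of exact single-site Gibbs over the prey path.

    Each v_t is drawn from its full conditional: Gaussian factors from
    the prey observation, the prey transitions into years t and t+1 and
    (piecewise, via the regime indicator at theta) the predator
    transition into year t+1.  ``u01`` is a (T, 2) array of uniforms:
    column 0 picks the regime branch, column 1 feeds the
    truncated-normal inverse CDF.  Updates ``v`` in place.
    """
    T = v.shape[0]
    sp_u, _, sp_v, so_v = sig[0], sig[1], sig[2], sig[3]
    acc_v = cq[1]
    acv = cq[2]
    tau_v2 = sp_v * sp_v
    tau_u2 = sp_u * sp_u
    for step in range(T):
        t = T - 1 - step if backward else step
        lam = 1.0 / (so_v * so_v)
        mw = y_v[t] / (so_v * so_v)
        if t == 0:
            lam += 1.0 / (s0v * s0v)
            mw += m0v / (s0v * s0v)
        else:
            usrc = u[t] if prey_same_year else u[t - 1]
            cv = cq[0] + acc_v * v[t - 1] + acv * usrc + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
            lam += 1.0 / tau_v2
            mw += cv / tau_v2
        if t <= T - 2:
            usrc2 = u[t + 1] if prey_same_year else u[t]
            d = v[t + 1] - (cq[0] + acv * usrc2 + cq[3] * st[t] + cq[4] * nao[t])
            lam += acc_v * acc_v / tau_v2
            mw += acc_v * d / tau_v2
        # predator transition into t+1 depends on v_t (and its regime)
        if t <= T - 2:
            base = cp[1] * u[t] + cp[3] * st[t] + cp[4] * nao[t]
            if has_threshold:
                best = 0
                logw = np.empty(2)
                mus = np.empty(2)
                lams = np.empty(2)
                for k in range(2):
                    if k == 0:
                        a0u, acu = cp[0], cp[2]
                    else:
                        a0u, acu = cp[5], cp[6]
                    dk = u[t + 1] - a0u - base
                    lam_k = lam + acu * acu / tau_u2
                    mw_k = mw + acu * dk / tau_u2
                    mu_k = mw_k / lam_k
                    sd_k = 1.0 / math.sqrt(lam_k)
                    z = (theta - mu_k) / sd_k
                    if k == 0:
                        mass = _phi(z)
                    else:
                        mass = 1.0 - _phi(z)
                    if mass <= 0.0:
                        logw[k] = -np.inf
                    else:
                        logw[k] = (
                            0.5 * mu_k * mu_k * lam_k
                            - 0.5 * dk * dk / tau_u2
                            - 0.5 * math.log(lam_k)
                            + math.log(mass)
                        )
                    mus[k] = mu_k
                    lams[k] = lam_k
                if logw[0] == -np.inf and logw[1] == -np.inf:
                    # numerically degenerate: keep current value
                    continue
                mx = max(logw[0], logw[1])
                w0 = math.exp(logw[0] - mx)
                w1 = math.exp(logw[1] - mx)
                k = 0 if u01[t, 0] < w0 / (w0 + w1) else 1
                mu_k = mus[k]
                sd_k = 1.0 / math.sqrt(lams[k])
                z = (theta - mu_k) / sd_k
                if k == 0:
                    lo, hi = 0.0, _phi(z)
                else:
                    lo, hi = _phi(z), 1.0
                pq = lo + u01[t, 1] * (hi - lo)
                if pq <= 0.0:
                    pq = 1e-300
                if pq >= 1.0:
                    pq = 1.0 - 1e-16
                v[t] = mu_k + sd_k * _ndtri(pq)
            else:
                acu = cp[2]
                dk = u[t + 1] - cp[0] - base
                lam_k = lam + acu * acu / tau_u2
                mw_k = mw + acu * dk / tau_u2
                mu_k = mw_k / lam_k
                v[t] = mu_k + _ndtri(u01[t, 1]) / math.sqrt(lam_k)
        else:
            mu_k = mw / lam
            v[t] = mu_k + _ndtri(u01[t, 1]) / math.sqrt(lam)
    return v


@njit(cache=True)
def eta_from_x(x, st, nao, cp, cq, sig, theta_p, has_thr_p, theta_q, has_thr_q,
               prey_same_year):
    """Standardized process innovations implied by a latent trajectory.

    The non-centered view of the state space: eta[t] holds the two
    species' process shocks (in sd units) driving the transition into
    year t+1.  Together with x[0] and the parameters this determines the
    trajectory bijectively (the map has constant Jacobian even across
    regime boundaries, since regimes only shift conditional means).
    """
    T = x.shape[0]
    eta = np.empty((T - 1, 2))
    for t in range(1, T):
        up = has_thr_p and x[t - 1, 1] >= theta_p
        a0u = cp[5] if up else cp[0]
        acu = cp[6] if up else cp[2]
        mu_u = a0u + cp[1] * x[t - 1, 0] + acu * x[t - 1, 1] + cp[3] * st[t - 1] + cp[4] * nao[t - 1]
        eta[t - 1, 0] = (x[t, 0] - mu_u) / sig[0]
        partner = x[t, 0] if prey_same_year else x[t - 1, 0]
        uq = has_thr_q and partner >= theta_q
        a0v = cq[5] if uq else cq[0]
        acv = cq[6] if uq else cq[2]
        mu_v = a0v + cq[1] * x[t - 1, 1] + acv * partner + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
        eta[t - 1, 1] = (x[t, 1] - mu_v) / sig[2]
    return eta


@njit(cache=True)
def x_from_eta(x0u, x0v, eta, st, nao, cp, cq, sig, theta_p, has_thr_p,
               theta_q, has_thr_q, prey_same_year):
    """Rebuild a latent trajectory from standardized innovations."""
    T = eta.shape[0] + 1
    x = np.empty((T, 2))
    x[0, 0] = x0u
    x[0, 1] = x0v
    for t in range(1, T):
        up = has_thr_p and x[t - 1, 1] >= theta_p
        a0u = cp[5] if up else cp[0]
        acu = cp[6] if up else cp[2]
        mu_u = a0u + cp[1] * x[t - 1, 0] + acu * x[t - 1, 1] + cp[3] * st[t - 1] + cp[4] * nao[t - 1]
        x[t, 0] = mu_u + sig[0] * eta[t - 1, 0]
        partner = x[t, 0] if prey_same_year else x[t - 1, 0]
        uq = has_thr_q and partner >= theta_q
        a0v = cq[5] if uq else cq[0]
        acv = cq[6] if uq else cq[2]
        mu_v = a0v + cq[1] * x[t - 1, 1] + acv * partner + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
        x[t, 1] = mu_v + sig[2] * eta[t - 1, 1]
    return x


@njit(cache=True)
def pred_transition_ll(u, v, st, nao, rp, cp, sig_proc_u):
    """Sum of predator-transition log densities for a given prey path
    and regime sequence."""
    T = u.shape[0]
    ll = 0.0
    for t in range(1, T):
        if rp[t] == 0:
            a0u, acu = cp[0], cp[2]
        else:
            a0u, acu = cp[5], cp[6]
        mu = a0u + cp[1] * u[t - 1] + acu * v[t - 1] + cp[3] * st[t - 1] + cp[4] * nao[t - 1]
        e = u[t] - mu
        ll += -0.5 * (_LOG_2PI + 2.0 * math.log(sig_proc_u) + (e / sig_proc_u) ** 2)
    return ll


@njit(cache=True)
def prey_cond_ffbs(y_v, u, st, nao, rp, cp, cq, sig, m0v, s0v, prey_same_year, eps):
    """Exact scalar FFBS draw of the prey path given the predator path,
    under a pinned predator-regime sequence ``rp``.

    Two observation streams attach to each prey state: the prey survey
    (sd sigma_obs_prey) and the next predator transition (a linear
    observation of v_t with the pinned regime's prey coefficient and sd
    sigma_proc_pred).  Returns the draw and the stream marginal
    log-likelihood used in the Metropolis correction across regime
    sequences.
    """
    T = y_v.shape[0]
    sp_u, sp_v, so_v = sig[0], sig[2], sig[3]
    acc_v = cq[1]
    acv = cq[2]
    mf = np.empty(T)
    pf = np.empty(T)
    ll = 0.0
    m = m0v
    p = s0v * s0v
    for t in range(T):
        if t > 0:
            usrc = u[t] if prey_same_year else u[t - 1]
            cv = cq[0] + acv * usrc + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
            m = cv + acc_v * m
            p = acc_v * acc_v * p + sp_v * sp_v
        # prey survey observation
        s = p + so_v * so_v
        ll += -0.5 * (_LOG_2PI + math.log(s) + (y_v[t] - m) ** 2 / s)
        k = p / s
        m = m + k * (y_v[t] - m)
        p = p * (1.0 - k)
        # predator transition into t+1 observes v_t (pinned regime)
        if t <= T - 2:
            if rp[t + 1] == 0:
                a0u, acu = cp[0], cp[2]
            else:
                a0u, acu = cp[5], cp[6]
            r = u[t + 1] - (a0u + cp[1] * u[t] + cp[3] * st[t] + cp[4] * nao[t])
            s = acu * acu * p + sp_u * sp_u
            ll += -0.5 * (_LOG_2PI + math.log(s) + (r - acu * m) ** 2 / s)
            k = p * acu / s
            m = m + k * (r - acu * m)
            p = p * (1.0 - k * acu)
        mf[t] = m
        pf[t] = p
    v = np.empty(T)
    v[T - 1] = mf[T - 1] + math.sqrt(max(pf[T - 1], 0.0)) * eps[T - 1]
    for t in range(T - 2, -1, -1):
        usrc = u[t + 1] if prey_same_year else u[t]
        cv = cq[0] + acv * usrc + cq[3] * st[t] + cq[4] * nao[t]
        pp = acc_v * acc_v * pf[t] + sp_v * sp_v
        j = pf[t] * acc_v / pp
        mean = mf[t] + j * (v[t + 1] - (cv + acc_v * mf[t]))
        var = pf[t] - j * j * pp
        v[t] = mean + math.sqrt(max(var, 0.0)) * eps[t]
    return v, ll


@njit(cache=True)
def _trunc_pair(m1, m2, p11, p12, p22, theta, side, u0, u1, xe0, xe1, eval_mode):
    """Sample (or evaluate) one backward step with the prey coordinate
    truncated to one side of theta.  Returns (u, v, log truncation mass).
    """
    sdv = math.sqrt(max(p22, 1e-300))
    logz = 0.0
    if side >= 0:
        z = (theta - m2) / sdv
        pz = _phi(z)
        mass = pz if side == 0 else 1.0 - pz
        if mass < 1e-290:
            mass = 1e-290
        logz = math.log(mass)
        if eval_mode:
            v = xe1
        else:
            if side == 0:
                lo, hi = 0.0, pz
            else:
                lo, hi = pz, 1.0
            p = lo + u1 * (hi - lo)
            if p <= 0.0:
                p = 1e-300
            if p >= 1.0:
                p = 1.0 - 1e-16
            v = m2 + sdv * _ndtri(p)
    else:
        v = xe1 if eval_mode else m2 + sdv * _ndtri(min(max(u1, 1e-300), 1.0 - 1e-16))
    mu_u = m1 + (p12 / max(p22, 1e-300)) * (v - m2)
    var_u = p11 - p12 * p12 / max(p22, 1e-300)
    sdu = math.sqrt(max(var_u, 1e-300))
    if eval_mode:
        u = xe0
    else:
        u = mu_u + sdu * _ndtri(min(max(u0, 1e-300), 1.0 - 1e-16))
    return u, v, logz


@njit(cache=True)
def ffbs_trunc(mf, Pf, st, nao, rp, rq, cp, cq, sig, prey_same_year,
               theta, side, u01, x_eval, eval_mode):
    """Backward sampling with the prey path confined to its current
    regime sides (no regime flips possible), or, in eval mode, the log
    truncation mass of an existing trajectory under the same recursion.

    ``side[t]`` is the required side of theta for the prey value at
    year t (0 lower, 1 upper, -1 unconstrained); ``u01`` supplies (T, 2)
    uniforms.  Returns ``(x, log_mass)``.
    """
    T = mf.shape[0]
    x = np.empty((T, 2))
    logW = 0.0
    u, v, lz = _trunc_pair(
        mf[T - 1, 0], mf[T - 1, 1], Pf[T - 1, 0], Pf[T - 1, 1], Pf[T - 1, 2],
        theta, side[T - 1], u01[T - 1, 0], u01[T - 1, 1],
        x_eval[T - 1, 0], x_eval[T - 1, 1], eval_mode,
    )
    x[T - 1, 0], x[T - 1, 1] = u, v
    logW += lz
    for t in range(T - 2, -1, -1):
        cu, c2, a11, a12, a21, a22, q11, q12, q22 = _transition(
            t + 1, rp, rq, cp, cq, sig, st, nao, prey_same_year
        )
        p11, p12, p22 = Pf[t, 0], Pf[t, 1], Pf[t, 2]
        m1, m2 = mf[t, 0], mf[t, 1]
        mp1 = cu + a11 * m1 + a12 * m2
        mp2 = c2 + a21 * m1 + a22 * m2
        t11 = a11 * p11 + a12 * p12
        t12 = a11 * p12 + a12 * p22
        t21 = a21 * p11 + a22 * p12
        t22 = a21 * p12 + a22 * p22
        pp11 = t11 * a11 + t12 * a12 + q11
        pp12 = t11 * a21 + t12 * a22 + q12
        pp22 = t21 * a21 + t22 * a22 + q22
        det = pp11 * pp22 - pp12 * pp12
        if det <= 1e-300:
            det = 1e-300
        i11 = pp22 / det
        i12 = -pp12 / det
        i22 = pp11 / det
        c11c = p11 * a11 + p12 * a12
        c12c = p11 * a21 + p12 * a22
        c21c = p12 * a11 + p22 * a12
        c22c = p12 * a21 + p22 * a22
        j11 = c11c * i11 + c12c * i12
        j12 = c11c * i12 + c12c * i22
        j21 = c21c * i11 + c22c * i12
        j22 = c21c * i12 + c22c * i22
        e1 = x[t + 1, 0] - mp1
        e2 = x[t + 1, 1] - mp2
        cm1 = m1 + j11 * e1 + j12 * e2
        cm2 = m2 + j21 * e1 + j22 * e2
        cv11 = p11 - (j11 * c11c + j12 * c12c)
        cv12 = p12 - (j11 * c21c + j12 * c22c)
        cv22 = p22 - (j21 * c21c + j22 * c22c)
        u, v, lz = _trunc_pair(
            cm1, cm2, cv11, cv12, cv22, theta, side[t],
            u01[t, 0], u01[t, 1], x_eval[t, 0], x_eval[t, 1], eval_mode,
        )
        x[t, 0], x[t, 1] = u, v
        logW += lz
    return x, logW


@njit(cache=True)
def prey_window_ffbs(y_v, u, st, nao, rp, cp, cq, sig, m0v, s0v,
                     prey_same_year, eps, s, e, v):
    """Conditional FFBS draw of the prey path over the window [s, e],
    given the predator path, the prey values outside the window, and a
    pinned predator-regime sequence.

    Returns the window draw and the window's stream marginal
    log-likelihood (used in the Metropolis correction across regime
    sequences).  Localizing redraws keeps the number of potential
    regime flips per proposal small, so acceptance stays high at any
    series length.
    """
    T = y_v.shape[0]
    sp_u, sp_v, so_v = sig[0], sig[2], sig[3]
    acc_v = cq[1]
    acv = cq[2]
    L = e - s + 1
    mf = np.empty(L)
    pf = np.empty(L)
    ll = 0.0
    if s == 0:
        m = m0v
        p = s0v * s0v
    else:
        usrc = u[s] if prey_same_year else u[s - 1]
        m = cq[0] + acc_v * v[s - 1] + acv * usrc + cq[3] * st[s - 1] + cq[4] * nao[s - 1]
        p = sp_v * sp_v
    for k in range(L):
        g = s + k
        if k > 0:
            usrc = u[g] if prey_same_year else u[g - 1]
            c = cq[0] + acv * usrc + cq[3] * st[g - 1] + cq[4] * nao[g - 1]
            m = c + acc_v * m
            p = acc_v * acc_v * p + sp_v * sp_v
        # prey survey
        sv = p + so_v * so_v
        ll += -0.5 * (_LOG_2PI + math.log(sv) + (y_v[g] - m) ** 2 / sv)
        kk = p / sv
        m = m + kk * (y_v[g] - m)
        p = p * (1.0 - kk)
        # predator transition into g+1 observes v_g
        if g <= T - 2:
            if rp[g + 1] == 0:
                a0u, acu = cp[0], cp[2]
            else:
                a0u, acu = cp[5], cp[6]
            r = u[g + 1] - (a0u + cp[1] * u[g] + cp[3] * st[g] + cp[4] * nao[g])
            sv = acu * acu * p + sp_u * sp_u
            ll += -0.5 * (_LOG_2PI + math.log(sv) + (r - acu * m) ** 2 / sv)
            kk = p * acu / sv
            m = m + kk * (r - acu * m)
            p = p * (1.0 - kk * acu)
        # right boundary: the prey transition out of the window
        if g == e and e <= T - 2:
            usrc = u[e + 1] if prey_same_year else u[e]
            r = v[e + 1] - (cq[0] + acv * usrc + cq[3] * st[e] + cq[4] * nao[e])
            sv = acc_v * acc_v * p + sp_v * sp_v
            ll += -0.5 * (_LOG_2PI + math.log(sv) + (r - acc_v * m) ** 2 / sv)
            kk = p * acc_v / sv
            m = m + kk * (r - acc_v * m)
            p = p * (1.0 - kk * acc_v)
        mf[k] = m
        pf[k] = p
    out = np.empty(L)
    out[L - 1] = mf[L - 1] + math.sqrt(max(pf[L - 1], 0.0)) * eps[L - 1]
    for k in range(L - 2, -1, -1):
        g = s + k
        usrc = u[g + 1] if prey_same_year else u[g]
        c = cq[0] + acv * usrc + cq[3] * st[g] + cq[4] * nao[g]
        pp = acc_v * acc_v * pf[k] + sp_v * sp_v
        j = pf[k] * acc_v / pp
        mean = mf[k] + j * (out[k + 1] - (c + acc_v * mf[k]))
        var = pf[k] - j * j * pp
        out[k] = mean + math.sqrt(max(var, 0.0)) * eps[k]
    return out, ll


@njit(cache=True)
def prey_ffbs_trunc(y_v, u, st, nao, rp, cp, cq, sig, m0v, s0v,
                    prey_same_year, theta, side, u01, v_eval, eval_mode):
    """Truncated conditional FFBS of the whole prey path given the
    predator path: each prey value is confined to its current regime
    side of theta, so the pinned regime sequence is preserved by
    construction.  Returns (draw, stream marginal loglik, log truncation
    mass); in eval mode the mass of an existing path is computed.
    """
    T = y_v.shape[0]
    sp_u, sp_v, so_v = sig[0], sig[2], sig[3]
    acc_v = cq[1]
    acv = cq[2]
    mf = np.empty(T)
    pf = np.empty(T)
    ll = 0.0
    m = m0v
    p = s0v * s0v
    for t in range(T):
        if t > 0:
            usrc = u[t] if prey_same_year else u[t - 1]
            c = cq[0] + acv * usrc + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
            m = c + acc_v * m
            p = acc_v * acc_v * p + sp_v * sp_v
        s = p + so_v * so_v
        ll += -0.5 * (_LOG_2PI + math.log(s) + (y_v[t] - m) ** 2 / s)
        k = p / s
        m = m + k * (y_v[t] - m)
        p = p * (1.0 - k)
        if t <= T - 2:
            if rp[t + 1] == 0:
                a0u, acu = cp[0], cp[2]
            else:
                a0u, acu = cp[5], cp[6]
            r = u[t + 1] - (a0u + cp[1] * u[t] + cp[3] * st[t] + cp[4] * nao[t])
            s = acu * acu * p + sp_u * sp_u
            ll += -0.5 * (_LOG_2PI + math.log(s) + (r - acu * m) ** 2 / s)
            k = p * acu / s
            m = m + k * (r - acu * m)
            p = p * (1.0 - k * acu)
        mf[t] = m
        pf[t] = p
    v = np.empty(T)
    logW = 0.0

    def _draw(mean, var, t):
        nonlocal logW
        sd = math.sqrt(max(var, 1e-300))
        if side[t] >= 0:
            z = (theta - mean) / sd
            pz = _phi(z)
            mass = pz if side[t] == 0 else 1.0 - pz
            if mass < 1e-290:
                mass = 1e-290
            logW += math.log(mass)
            if eval_mode:
                return v_eval[t]
            if side[t] == 0:
                lo, hi = 0.0, pz
            else:
                lo, hi = pz, 1.0
            pq = lo + u01[t] * (hi - lo)
            if pq <= 0.0:
                pq = 1e-300
            if pq >= 1.0:
                pq = 1.0 - 1e-16
            return mean + sd * _ndtri(pq)
        if eval_mode:
            return v_eval[t]
        pq = min(max(u01[t], 1e-300), 1.0 - 1e-16)
        return mean + sd * _ndtri(pq)

    v[T - 1] = _draw(mf[T - 1], pf[T - 1], T - 1)
    for t in range(T - 2, -1, -1):
        usrc = u[t + 1] if prey_same_year else u[t]
        c = cq[0] + acv * usrc + cq[3] * st[t] + cq[4] * nao[t]
        pp = acc_v * acc_v * pf[t] + sp_v * sp_v
        j = pf[t] * acc_v / pp
        mean = mf[t] + j * (v[t + 1] - (c + acc_v * mf[t]))
        var = pf[t] - j * j * pp
        v[t] = _draw(mean, var, t)
    return v, ll, logW


@njit(cache=True)
def prey_ffbs_invert(y_v, u, st, nao, rp, cp, cq, sig, m0v, s0v,
                     prey_same_year, v):
    """Invert the conditional prey FFBS: recover the standard-normal
    innovations that reproduce ``v`` under the given parameters and
    pinned regimes, together with the stream marginal log-likelihood.

    Holding these innovations fixed while moving the variance
    parameters transports the path smoothly, which makes variance moves
    behave like updates on the marginal posterior.
    """
    T = y_v.shape[0]
    sp_u, sp_v, so_v = sig[0], sig[2], sig[3]
    acc_v = cq[1]
    acv = cq[2]
    mf = np.empty(T)
    pf = np.empty(T)
    ll = 0.0
    m = m0v
    p = s0v * s0v
    for t in range(T):
        if t > 0:
            usrc = u[t] if prey_same_year else u[t - 1]
            c = cq[0] + acv * usrc + cq[3] * st[t - 1] + cq[4] * nao[t - 1]
            m = c + acc_v * m
            p = acc_v * acc_v * p + sp_v * sp_v
        s = p + so_v * so_v
        ll += -0.5 * (_LOG_2PI + math.log(s) + (y_v[t] - m) ** 2 / s)
        k = p / s
        m = m + k * (y_v[t] - m)
        p = p * (1.0 - k)
        if t <= T - 2:
            if rp[t + 1] == 0:
                a0u, acu = cp[0], cp[2]
            else:
                a0u, acu = cp[5], cp[6]
            r = u[t + 1] - (a0u + cp[1] * u[t] + cp[3] * st[t] + cp[4] * nao[t])
            s = acu * acu * p + sp_u * sp_u
            ll += -0.5 * (_LOG_2PI + math.log(s) + (r - acu * m) ** 2 / s)
            k = p * acu / s
            m = m + k * (r - acu * m)
            p = p * (1.0 - k * acu)
        mf[t] = m
        pf[t] = p
    eps = np.empty(T)
    eps[T - 1] = (v[T - 1] - mf[T - 1]) / math.sqrt(max(pf[T - 1], 1e-300))
    for t in range(T - 2, -1, -1):
        usrc = u[t + 1] if prey_same_year else u[t]
        c = cq[0] + acv * usrc + cq[3] * st[t] + cq[4] * nao[t]
        pp = acc_v * acc_v * pf[t] + sp_v * sp_v
        j = pf[t] * acc_v / pp
        mean = mf[t] + j * (v[t + 1] - (c + acc_v * mf[t]))
        var = pf[t] - j * j * pp
        eps[t] = (v[t] - mean) / math.sqrt(max(var, 1e-300))
    return eps, ll
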