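"""Joint Bayesian estimation of the two-species state-space model.

The joint posterior is over both species' process/observation parameters
and the latent log-abundance trajectories.  The threshold regime of the
predator equation is defined by the *latent* prey state, and the sampler
targets that model exactly.  The key structural facts it exploits:

* given the prey path, the predator chain is linear-Gaussian (its
  regimes are determined), and each prey transition is a linear
  observation of the predator state -> exact scalar FFBS draw;
* given the predator path, each prey state's full conditional is a
  two-branch truncated-Gaussian mixture (the branch is the regime of
  the next predator transition) -> exact single-site Gibbs, plus
  windowed conditional FFBS redraws under a pinned regime sequence with
  an exact Metropolis correction for regime flips;
* given the latent paths, all regression coefficients are conditionally
  conjugate -> exact Gaussian draws;
* the variance blocks move both conditionally (adaptive random walk
  given the paths) and marginally: a fresh-path move with exact flip
  correction, and a whitened move that holds the smoother innovations
  fixed and transports the path deterministically as the variances
  move, which makes the acceptance ratio the marginal posterior ratio.

Several of these updates are composed per recorded iteration, so the
chain layout (chains x iterations, burn-in, thinning) can stay at the
configured values while each iteration performs enough work to mix.

Priors: Normal(0, 5) on all regression coefficients and intercepts,
half-Normal(0, 1) on each observation sd, and an informative
Normal(1, 0.5) truncated to positive values on the ratio
r = sigma_proc^2 / sigma_obs^2 per species (the two variances are not
separately identifiable from one series).  The initial latent state has
a Normal(first observed log abundance, 1) prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import _kalman
from .timeseries_io import AlignedDataset

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "JointModel",
    "PosteriorDraws",
    "PosteriorSummary",
    "build_joint_model",
    "fit",
    "summarize",
    "sensitivity_ratio_prior",
    "process_error_correlation",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Scales of the weakly informative priors (see module docstring)."""

    coef_scale: float = 5.0
    ratio_mean: float = 1.0
    ratio_sd: float = 0.5
    obs_sd_scale: float = 1.0
    init_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("coef_scale", "ratio_mean", "ratio_sd", "obs_sd_scale", "init_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout; defaults mirror a long-run configuration of four
    chains of 50 000 iterations, 30 000 burn-in, thinning by 10."""

    chains: int = 4
    iterations: int = 50_000
    burn_in: int = 30_000
    thin: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains")
        if not (0 < self.burn_in < self.iterations):
            raise ValueError("burn_in must be in (0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: (iterations - burn_in) / thin."""
        return (self.iterations - self.burn_in) // self.thin


def reduced_mcmc(seed: int | None = None, chains: int = 4) -> MCMCConfig:
    """Desk-scale MCMC settings (4 x 2000, burn-in 1000, no thinning)."""
    return MCMCConfig(chains=chains, iterations=2000, burn_in=1000, thin=1, seed=seed)


class JointModel:
    """Joint posterior over both species' parameters and latent states.

    Built by :func:`build_joint_model`; opaque to callers except for the
    density methods used by the sampler and tests.
    """

    def __init__(
        self,
        dataset: AlignedDataset,
        threshold_species: tuple[str, ...],
        theta: dict[str, float],
        priors: PriorConfig,
        sample_theta: bool = False,
    ):
        lag = dataset.lag
        if lag.predator_prey_lag != 1:
            raise NotImplementedError(
                "the joint model requires the predator to use the prey at year-1"
            )
        for sp in threshold_species:
            if sp not in ("predator", "prey"):
                raise ValueError(f"unknown species {sp!r} in threshold spec")
            if not sample_theta and sp not in theta:
                raise ValueError(f"threshold species {sp!r} needs a theta value")
        self.dataset = dataset
        self.priors = priors
        self.prey_same_year = lag.prey_predator_lag == 0
        self.pred_threshold = "predator" in threshold_species
        self.prey_threshold = "prey" in threshold_species
        self.theta_pred = theta.get("predator") if self.pred_threshold else None
        self.theta_prey = theta.get("prey") if self.prey_threshold else None
        self.sample_theta = sample_theta

        self.y = np.column_stack(
            [dataset.predator.log_values, dataset.prey.log_values]
        )
        self.T = dataset.n_years
        covs = dataset.covariates
        self.n_cov = min(len(covs), 2)
        self.st = covs[0].values if self.n_cov >= 1 else np.zeros(self.T)
        self.nao = covs[1].values if self.n_cov >= 2 else np.zeros(self.T)
        self.m0 = self.y[0].copy()
        self.s0 = np.array([priors.init_sd, priors.init_sd])
        if sample_theta:
            if self.pred_threshold:
                from .threshold import candidate_grid

                grid = candidate_grid(self.y[:-1, 1])
                self.theta_range = (float(grid[0]), float(grid[-1]))
            else:
                raise ValueError("sample_theta requires a threshold-typed predator")

        self.param_names = self._build_names()
        self._log_trunc = math.log(
            float(stats.norm.cdf(priors.ratio_mean / priors.ratio_sd))
        )
        self._build_unpack_maps()
        self._cache_regimes()

    # -- layout ---------------------------------------------------------

    def _build_names(self) -> list[str]:
        names = ["a_pred_0", "a_pred_self", "a_pred_prey"]
        if self.n_cov >= 1:
            names.append("a_pred_st")
        if self.n_cov >= 2:
            names.append("a_pred_nao")
        if self.pred_threshold:
            names += ["b_pred_0", "b_pred_prey"]
        names += ["a_prey_0", "a_prey_self", "a_prey_pred"]
        if self.n_cov >= 1:
            names.append("a_prey_st")
        if self.n_cov >= 2:
            names.append("a_prey_nao")
        if self.prey_threshold:
            names += ["b_prey_0", "b_prey_pred"]
        names += ["sigma_obs_pred", "ratio_pred", "sigma_obs_prey", "ratio_prey"]
        if self.sample_theta:
            names.append("theta_pred")
        return names

    @property
    def n_sampled(self) -> int:
        return len(self.param_names)

    @property
    def n_coef_pred(self) -> int:
        return 3 + self.n_cov + (2 if self.pred_threshold else 0)

    @property
    def n_coef_prey(self) -> int:
        return 3 + self.n_cov + (2 if self.prey_threshold else 0)

    @property
    def sigma_slice(self) -> slice:
        """Indices of the variance block (plus theta when sampled)."""
        start = self.n_coef_pred + self.n_coef_prey
        return slice(start, self.n_sampled)

    @property
    def n_parameters(self) -> int:
        """Structural parameter count: coefficients + two error sds per
        species, plus (b0, b_cross, theta) per threshold block."""
        n = 2 * (3 + self.n_cov + 2)
        if self.pred_threshold:
            n += 3
        if self.prey_threshold:
            n += 3
        return n

    @property
    def n_latent(self) -> int:
        return 2 * self.T

    def _cache_regimes(self) -> None:
        if not self.sample_theta:
            self._rp, self._rq = _kalman.regimes_from_series(
                self.y[:, 0],
                self.y[:, 1],
                self.theta_pred,
                self.theta_prey,
                self.prey_same_year,
            )

    # -- parameter transform --------------------------------------------

    def _build_unpack_maps(self) -> None:
        """Precompute index maps from the sampled vector to the 7-slot
        coefficient arrays of the Kalman kernels."""
        ncoef = 3 + self.n_cov
        slots = [0, 1, 2, 3, 4][: 3 + self.n_cov]
        i = 0
        cp_phi = list(range(i, i + ncoef))
        cp_slots = list(slots)
        i += ncoef
        if self.pred_threshold:
            cp_phi += [i, i + 1]
            cp_slots += [5, 6]
            i += 2
        cq_phi = list(range(i, i + ncoef))
        cq_slots = list(slots)
        i += ncoef
        if self.prey_threshold:
            cq_phi += [i, i + 1]
            cq_slots += [5, 6]
            i += 2
        self._cp_phi = np.array(cp_phi)
        self._cp_slots = np.array(cp_slots)
        self._cq_phi = np.array(cq_phi)
        self._cq_slots = np.array(cq_slots)
        self._n_coef_total = i
        pr = self.priors
        self._coef_prior_const = -0.5 * i * (
            _LOG_2PI + 2.0 * math.log(pr.coef_scale)
        )
        self._sig_prior_const = 2.0 * (
            math.log(2.0)
            - 0.5 * (_LOG_2PI + 2.0 * math.log(pr.obs_sd_scale))
            - 0.5 * (_LOG_2PI + 2.0 * math.log(pr.ratio_sd))
            - self._log_trunc
        )
        self._unpack_cache_key: bytes | None = None
        self._unpack_cache_val = None

    def unpack(self, phi: np.ndarray):
        """Unconstrained vector -> (cp, cq, sig, theta_p, log prior + Jacobian).

        ``cp``/``cq`` are the 7-slot coefficient arrays of the Kalman
        kernels; ``sig = [sig_proc_pred, sig_obs_pred, sig_proc_prey,
        sig_obs_prey]``.
        """
        key = phi.tobytes()
        if key == self._unpack_cache_key:
            return self._unpack_cache_val
        pr = self.priors
        nc = self._n_coef_total
        coefs = phi[:nc]
        logp = self._coef_prior_const - 0.5 * float(coefs @ coefs) / pr.coef_scale**2
        cp = np.zeros(7)
        cp[self._cp_slots] = phi[self._cp_phi]
        if not self.pred_threshold:
            cp[5], cp[6] = cp[0], cp[2]
        cq = np.zeros(7)
        cq[self._cq_slots] = phi[self._cq_phi]
        if not self.prey_threshold:
            cq[5], cq[6] = cq[0], cq[2]

        sig = np.empty(4)
        logp += self._sig_prior_const
        i = nc
        for k in range(2):
            log_so, log_r = phi[i], phi[i + 1]
            i += 2
            so = math.exp(log_so)
            r = math.exp(log_r)
            sig[2 * k + 1] = so
            sig[2 * k] = so * math.sqrt(r)
            z = (r - pr.ratio_mean) / pr.ratio_sd
            # half-Normal on sigma_obs, truncated Normal on the variance
            # ratio, plus the log-Jacobians of the log transforms
            logp += (
                -0.5 * (so / pr.obs_sd_scale) ** 2
                + log_so
                - 0.5 * z * z
                + log_r
            )

        theta_p = self.theta_pred
        if self.sample_theta:
            theta_p = float(phi[i])
            lo, hi = self.theta_range
            if not (lo <= theta_p <= hi):
                out = (cp, cq, sig, theta_p, -math.inf)
                self._unpack_cache_key = key
                self._unpack_cache_val = out
                return out
            logp += -math.log(hi - lo)
            i += 1
        out = (cp, cq, sig, theta_p, logp)
        self._unpack_cache_key = key
        self._unpack_cache_val = out
        return out

    def pack_start(self) -> np.ndarray:
        """Least-squares starting point on the unconstrained scale."""
        from .threshold import _design

        phi = []
        for species, thr, theta in (
            ("predator", self.pred_threshold, self.theta_pred),
            ("prey", self.prey_threshold, self.theta_prey),
        ):
            if thr and theta is None:  # sampled theta: start mid-grid
                theta = 0.5 * (self.theta_range[0] + self.theta_range[1])
            yv, X = _design(self.dataset, species, theta if thr else None)
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            if thr:
                # threshold design: [low, up, partner*low, partner*up, self, covs]
                a0, b0, ac, bc, aself = beta[0], beta[1], beta[2], beta[3], beta[4]
                covs = beta[5 : 5 + self.n_cov]
                phi += [a0, aself, ac, *covs, b0, bc]
            else:
                a0, ac, aself = beta[0], beta[1], beta[2]
                covs = beta[3 : 3 + self.n_cov]
                phi += [a0, aself, ac, *covs]
        phi += [math.log(0.2), 0.0, math.log(0.2), 0.0]
        if self.sample_theta:
            phi.append(0.5 * (self.theta_range[0] + self.theta_range[1]))
        return np.array(phi, dtype=float)

    # -- densities ------------------------------------------------------

    def _regimes(self, theta_p):
        if self.sample_theta:
            return _kalman.regimes_from_series(
                self.y[:, 0], self.y[:, 1], theta_p, self.theta_prey,
                self.prey_same_year,
            )
        return self._rp, self._rq

    def marginal_log_posterior(self, phi: np.ndarray):
        """log prior + Kalman marginal likelihood (observed-regime model).

        Returns ``(value, kf_state)`` where ``kf_state`` carries what
        FFBS needs; value is -inf outside the support.
        """
        cp, cq, sig, theta_p, logp = self.unpack(phi)
        if not np.isfinite(logp):
            return -math.inf, None
        rp, rq = self._regimes(theta_p)
        ll, mf, Pf = _kalman.kalman_filter(
            self.y, self.st, self.nao, rp, rq, cp, cq, sig,
            self.m0, self.s0, self.prey_same_year,
        )
        if not np.isfinite(ll):
            return -math.inf, None
        return logp + ll, (cp, cq, sig, rp, rq, mf, Pf)

    def latent_regimes(self, x: np.ndarray, theta_p=None):
        """Regime indicator arrays implied by a latent trajectory."""
        if theta_p is None:
            theta_p = self.theta_pred
        return _kalman.regimes_from_series(
            x[:, 0], x[:, 1],
            theta_p if self.pred_threshold else None,
            self.theta_prey,
            self.prey_same_year,
        )

    def _proc_ll(self, x, rp, rq, cp, cq, sig) -> float:
        return _kalman.process_loglik_latent(
            x, self.st, self.nao, rp, rq, cp, cq, sig, self.prey_same_year
        )

    def x_update(self, phi: np.ndarray, x: np.ndarray, rng) -> tuple[np.ndarray, bool]:
        """Metropolised FFBS refresh of the latent trajectories.

        The proposal is an exact smoother draw from the linear-Gaussian
        model whose regime sequence is pinned to the *current* latent
        prey path; the MH correction only involves transitions whose
        regime flips, so the acceptance probability is 1 whenever the
        proposed path keeps the regime sequence.
        """
        cp, cq, sig, theta_p, _ = self.unpack(phi)
        rp, rq = self.latent_regimes(x, theta_p)
        ll_z, mf, Pf = _kalman.kalman_filter(
            self.y, self.st, self.nao, rp, rq, cp, cq, sig,
            self.m0, self.s0, self.prey_same_year,
        )
        eps = rng.standard_normal((self.T, 2))
        x_new, _ = _kalman.ffbs(
            mf, Pf, self.st, self.nao, rp, rq, cp, cq, sig,
            self.prey_same_year, eps,
        )
        rp_new, rq_new = self.latent_regimes(x_new, theta_p)
        if np.array_equal(rp_new, rp) and np.array_equal(rq_new, rq):
            return x_new, True
        ll_z2, _, _ = _kalman.kalman_filter(
            self.y, self.st, self.nao, rp_new, rq_new, cp, cq, sig,
            self.m0, self.s0, self.prey_same_year,
        )
        if not np.isfinite(ll_z2):
            return x, False
        log_alpha = (
            self._proc_ll(x_new, rp_new, rq_new, cp, cq, sig)
            - self._proc_ll(x, rp, rq, cp, cq, sig)
            + self._proc_ll(x, rp_new, rq_new, cp, cq, sig)
            - self._proc_ll(x_new, rp, rq, cp, cq, sig)
            + ll_z
            - ll_z2
        )
        if math.log(rng.random()) < log_alpha:
            return x_new, True
        return x, False

    def sigma_marginal_update(
        self, phi: np.ndarray, x: np.ndarray, idx: np.ndarray,
        step: np.ndarray, rng, truncated: bool = True,
    ):
        """Marginal variance-block move with a joint latent redraw.

        The proposal draws a fresh trajectory from the exact smoother of
        the model pinned to the current latent regime sequence, so the
        move samples the Kalman-marginal posterior of the variance block
        up to an exact correction for regime flips.  Breaks the
        variance-path coupling that limits the conditional updates.
        """
        phi_new = phi.copy()
        phi_new[idx] = phi_new[idx] + step
        cp, cq, sig, thp, logp = self.unpack(phi)
        cpn, cqn, sign, thpn, logpn = self.unpack(phi_new)
        if not np.isfinite(logpn):
            return phi, x, False
        if self.prey_threshold or not truncated:
            return self._sigma_marginal_flip(phi, phi_new, x, rng)
        rp, rq = self.latent_regimes(x, thp)
        T = self.T
        side = np.full(T, -1, dtype=np.int64)
        if self.pred_threshold:
            side[: T - 1] = rp[1:]
        th_cur = thp if thp is not None else 0.0
        th_new = thpn if thpn is not None else 0.0
        ll_cur, mf0, Pf0 = _kalman.kalman_filter(
            self.y, self.st, self.nao, rp, rq, cp, cq, sig,
            self.m0, self.s0, self.prey_same_year,
        )
        ll_new, mf1, Pf1 = _kalman.kalman_filter(
            self.y, self.st, self.nao, rp, rq, cpn, cqn, sign,
            self.m0, self.s0, self.prey_same_year,
        )
        if not (np.isfinite(ll_cur) and np.isfinite(ll_new)):
            return phi, x, False
        dummy = np.empty((T, 2))
        _, logw_cur = _kalman.ffbs_trunc(
            mf0, Pf0, self.st, self.nao, rp, rq, cp, cq, sig,
            self.prey_same_year, th_cur, side, dummy, x, True,
        )
        x_new, logw_new = _kalman.ffbs_trunc(
            mf1, Pf1, self.st, self.nao, rp, rq, cpn, cqn, sign,
            self.prey_same_year, th_new, side, rng.random((T, 2)), dummy, False,
        )
        log_alpha = (logpn - logp) + (ll_new - ll_cur) + (logw_new - logw_cur)
        if math.log(rng.random()) < log_alpha:
            return phi_new, x_new, True
        return phi, x, False

    def _sigma_marginal_flip(self, phi, phi_new, x, rng):
        """Fallback marginal move (untruncated proposal with exact
        regime-flip correction), used when the prey is threshold-typed."""
        cp, cq, sig, thp, logp = self.unpack(phi)
        cpn, cqn, sign, thpn, logpn = self.unpack(phi_new)
        rp, rq = self.latent_regimes(x, thp)
        ll_new_z, mf, Pf = _kalman.kalman_filter(
            self.y, self.st, self.nao, rp, rq, cpn, cqn, sign,
            self.m0, self.s0, self.prey_same_year,
        )
        if not np.isfinite(ll_new_z):
            return phi, x, False
        x_new, _ = _kalman.ffbs(
            mf, Pf, self.st, self.nao, rp, rq, cpn, cqn, sign,
            self.prey_same_year, rng.standard_normal((self.T, 2)),
        )
        rp2, rq2 = self.latent_regimes(x_new, thpn)
        ll_cur2, _, _ = _kalman.kalman_filter(
            self.y, self.st, self.nao, rp2, rq2, cp, cq, sig,
            self.m0, self.s0, self.prey_same_year,
        )
        if not np.isfinite(ll_cur2):
            return phi, x, False
        log_alpha = (
            (logpn - logp)
            + ll_new_z
            - ll_cur2
            + self._proc_ll(x_new, rp2, rq2, cpn, cqn, sign)
            - self._proc_ll(x_new, rp, rq, cpn, cqn, sign)
            + self._proc_ll(x, rp2, rq2, cp, cq, sig)
            - self._proc_ll(x, rp, rq, cp, cq, sig)
        )
        if math.log(rng.random()) < log_alpha:
            return phi_new, x_new, True
        return phi, x, False

    def prey_window_update(self, cp, cq, sig, theta_p, x, rp, s, e, rng):
        """Metropolised conditional FFBS redraw of the prey path over
        window [s, e], with exact correction for regime flips inside the
        window.  Mutates ``x`` in place; returns the (possibly updated)
        predator regime array."""
        T = self.T
        v = x[:, 1]
        eps = rng.standard_normal(e - s + 1)
        v_w, ll_z = _kalman.prey_window_ffbs(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp, cp, cq, sig,
            self.m0[1], self.s0[1], self.prey_same_year, eps, s, e, v,
        )
        if not self.pred_threshold:
            v[s : e + 1] = v_w
            return rp
        v_new = v.copy()
        v_new[s : e + 1] = v_w
        rp_new = np.zeros(T, dtype=np.int64)
        rp_new[1:] = (v_new[:-1] >= theta_p).astype(np.int64)
        if np.array_equal(rp_new, rp):
            v[s : e + 1] = v_w
            return rp
        _, ll_z2 = _kalman.prey_window_ffbs(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp_new, cp, cq, sig,
            self.m0[1], self.s0[1], self.prey_same_year,
            np.zeros(e - s + 1), s, e, v,
        )
        h = _kalman.pred_transition_ll
        u = x[:, 0]
        log_alpha = (
            h(u, v_new, self.st, self.nao, rp_new, cp, sig[0])
            - h(u, v, self.st, self.nao, rp, cp, sig[0])
            + h(u, v, self.st, self.nao, rp_new, cp, sig[0])
            - h(u, v_new, self.st, self.nao, rp, cp, sig[0])
            + ll_z
            - ll_z2
        )
        if math.log(rng.random()) < log_alpha:
            v[s : e + 1] = v_w
            return rp_new
        return rp

    def pred_sigma_marginal(self, phi, phi_new, x, rp, rng):
        """Marginal move of the predator variance block: the predator
        path is integrated out exactly (its regimes depend only on the
        prey path, which is held fixed), so this is plain MH on the
        2-dim marginal with a fresh exact path draw."""
        _, _, sig, _, logp = self.unpack(phi)
        cpn, cqn, sign, _, logpn = self.unpack(phi_new)
        if not np.isfinite(logpn):
            return phi, False
        u_new, ll_new = _kalman.predator_ffbs(
            self.y[:, 0], x[:, 1], self.st, self.nao, rp, cpn, cqn, sign,
            self.m0[0], self.s0[0], self.prey_same_year,
            rng.standard_normal(self.T),
        )
        cp, cq, _, _, _ = self.unpack(phi)
        _, ll_cur = _kalman.predator_ffbs(
            self.y[:, 0], x[:, 1], self.st, self.nao, rp, cp, cq, sig,
            self.m0[0], self.s0[0], self.prey_same_year, np.zeros(self.T),
        )
        if math.log(rng.random()) < (logpn - logp) + (ll_new - ll_cur):
            x[:, 0] = u_new
            return phi_new, True
        return phi, False

    def prey_sigma_marginal(self, phi, phi_new, x, rp, theta_p, rng):
        """Marginal move of the prey variance block: the prey path is
        integrated out under the pinned regime sequence with an exact
        Metropolis correction for regime flips in the proposed path."""
        cp, cq, sig, _, logp = self.unpack(phi)
        cpn, cqn, sign, _, logpn = self.unpack(phi_new)
        if not np.isfinite(logpn):
            return phi, rp, False
        T = self.T
        v = x[:, 1]
        v_new, ll_new = _kalman.prey_window_ffbs(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp, cpn, cqn, sign,
            self.m0[1], self.s0[1], self.prey_same_year,
            rng.standard_normal(T), 0, T - 1, v,
        )
        if self.pred_threshold:
            rp_new = np.zeros(T, dtype=np.int64)
            rp_new[1:] = (v_new[:-1] >= theta_p).astype(np.int64)
        else:
            rp_new = rp
        _, ll_cur = _kalman.prey_window_ffbs(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp_new, cp, cq, sig,
            self.m0[1], self.s0[1], self.prey_same_year,
            np.zeros(T), 0, T - 1, v,
        )
        log_alpha = (logpn - logp) + (ll_new - ll_cur)
        if self.pred_threshold and not np.array_equal(rp_new, rp):
            h = _kalman.pred_transition_ll
            u = x[:, 0]
            log_alpha += (
                h(u, v_new, self.st, self.nao, rp_new, cp, sig[0])
                - h(u, v, self.st, self.nao, rp, cp, sig[0])
                + h(u, v, self.st, self.nao, rp_new, cp, sig[0])
                - h(u, v_new, self.st, self.nao, rp, cp, sig[0])
            )
        if math.log(rng.random()) < log_alpha:
            x[:, 1] = v_new
            return phi_new, rp_new, True
        return phi, rp, False

    def prey_sigma_marginal_trunc(self, phi, phi_new, x, rp, theta_p, rng):
        """Truncated variant of the prey variance-block marginal move:
        the proposed prey path is confined to its current regime sides,
        so no flip correction is needed; the truncation masses enter
        the acceptance ratio exactly.  Complements the flip variant
        (this one excels when regime flips would be costly)."""
        cp, cq, sig, _, logp = self.unpack(phi)
        cpn, cqn, sign, _, logpn = self.unpack(phi_new)
        if not np.isfinite(logpn):
            return phi, False
        T = self.T
        v = x[:, 1]
        side = np.full(T, -1, dtype=np.int64)
        if self.pred_threshold:
            side[: T - 1] = rp[1:]
        th = theta_p if theta_p is not None else 0.0
        dummy = np.empty(T)
        _, ll_cur, logw_cur = _kalman.prey_ffbs_trunc(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp, cp, cq, sig,
            self.m0[1], self.s0[1], self.prey_same_year, th, side,
            dummy, v, True,
        )
        v_new, ll_new, logw_new = _kalman.prey_ffbs_trunc(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp, cpn, cqn, sign,
            self.m0[1], self.s0[1], self.prey_same_year, th, side,
            rng.random(T), dummy, False,
        )
        log_alpha = (logpn - logp) + (ll_new - ll_cur) + (logw_new - logw_cur)
        if math.log(rng.random()) < log_alpha:
            x[:, 1] = v_new
            return phi_new, True
        return phi, False

    def prey_sigma_marginal_white(self, phi, phi_new, x, rp, theta_p, rng):
        """Whitened marginal move of the prey variance block: the
        smoother innovations of the current prey path are held fixed
        while the variances move, transporting the path deterministically.
        The acceptance ratio is then exactly the marginal posterior
        ratio; proposals whose transported path would flip a regime are
        rejected (the transport is only a bijection within a regime
        configuration)."""
        cp, cq, sig, _, logp = self.unpack(phi)
        cpn, cqn, sign, _, logpn = self.unpack(phi_new)
        if not np.isfinite(logpn):
            return phi, False
        T = self.T
        v = x[:, 1]
        eps, ll_cur = _kalman.prey_ffbs_invert(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp, cp, cq, sig,
            self.m0[1], self.s0[1], self.prey_same_year, v,
        )
        v_new, ll_new = _kalman.prey_window_ffbs(
            self.y[:, 1], x[:, 0], self.st, self.nao, rp, cpn, cqn, sign,
            self.m0[1], self.s0[1], self.prey_same_year, eps, 0, T - 1, v,
        )
        if self.pred_threshold:
            rp_new = np.zeros(T, dtype=np.int64)
            rp_new[1:] = (v_new[:-1] >= theta_p).astype(np.int64)
            if not np.array_equal(rp_new, rp):
                return phi, False
        if math.log(rng.random()) < (logpn - logp) + (ll_new - ll_cur):
            x[:, 1] = v_new
            return phi_new, True
        return phi, False

    def sigma_logpost(self, phi: np.ndarray, x: np.ndarray) -> float:
        """Log density of the variance block given latent states:
        prior (incl. Jacobians) + process + observation terms."""
        cp, cq, sig, theta_p, logp = self.unpack(phi)
        if not np.isfinite(logp):
            return -math.inf
        rp, rq = self.latent_regimes(x, theta_p)
        total = logp + self._proc_ll(x, rp, rq, cp, cq, sig)
        for k in (0, 1):
            so = sig[2 * k + 1]
            resid = self.y[:, k] - x[:, k]
            total += -0.5 * self.T * (_LOG_2PI + 2.0 * math.log(so)) - 0.5 * float(
                resid @ resid
            ) / so**2
        return total

    def gibbs_coefficients(
        self, phi: np.ndarray, x: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Exact draw of all regression coefficients given latent states.

        Conditional on the latent trajectories (whose prey path fixes
        the regime sequence) and the process sds, each species' process
        equation is a Gaussian linear regression with a Normal(0,
        coef_scale^2) prior, so the full conditional is Gaussian and is
        sampled exactly.
        """
        cp, cq, sig, theta_p, _ = self.unpack(phi)
        phi = phi.copy()
        T = self.T
        t = np.arange(1, T)
        st = self.st[t - 1]
        nao = self.nao[t - 1]
        tau = 1.0 / self.priors.coef_scale**2

        offset = 0
        for species in ("predator", "prey"):
            if species == "predator":
                resp = x[t, 0]
                own_prev = x[t - 1, 0]
                partner = x[t - 1, 1]
                thr = self.pred_threshold
                theta = theta_p
                s_proc = sig[0]
                ncoef = self.n_coef_pred
            else:
                resp = x[t, 1]
                own_prev = x[t - 1, 1]
                partner = x[t, 0] if self.prey_same_year else x[t - 1, 0]
                thr = self.prey_threshold
                theta = self.theta_prey
                s_proc = sig[2]
                ncoef = self.n_coef_prey
            cols = []
            if thr:
                upper = partner >= theta
                lower = ~upper
                cols = [lower.astype(float), own_prev, partner * lower]
                covcols = [st, nao][: self.n_cov]
                cols += covcols
                cols += [upper.astype(float), partner * upper]
            else:
                cols = [np.ones_like(resp), own_prev, partner]
                cols += [st, nao][: self.n_cov]
            X = np.column_stack(cols)
            prec = X.T @ X / s_proc**2 + tau * np.eye(X.shape[1])
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, X.T @ resp / s_proc**2)
            z = rng.standard_normal(X.shape[1])
            beta = mean + np.linalg.solve(L.T, z)
            phi[offset : offset + ncoef] = beta
            offset += ncoef
        return phi

    def noncentered_logpost(self, phi: np.ndarray, x0: np.ndarray, eta: np.ndarray):
        """Log density of the variance block in the non-centered
        parameterization (standardized innovations held fixed).

        Returns ``(value, rebuilt trajectory)``; the process terms are
        constant in this view, so the target is prior + observation
        log-likelihood of the rebuilt trajectory.
        """
        cp, cq, sig, theta_p, logp = self.unpack(phi)
        if not np.isfinite(logp):
            return -math.inf, None
        x = _kalman.x_from_eta(
            x0[0], x0[1], eta, self.st, self.nao, cp, cq, sig,
            theta_p if theta_p is not None else 0.0, self.pred_threshold,
            self.theta_prey if self.theta_prey is not None else 0.0,
            self.prey_threshold, self.prey_same_year,
        )
        total = logp
        for k in (0, 1):
            so = sig[2 * k + 1]
            resid = self.y[:, k] - x[:, k]
            total += -0.5 * self.T * (_LOG_2PI + 2.0 * math.log(so)) - 0.5 * float(
                resid @ resid
            ) / so**2
        return total, x

    def obs_noncentered_logpost(self, phi: np.ndarray, xi: np.ndarray):
        """Variance-block log density with the *observation* residuals
        (in sd units) held fixed: latent states are rebuilt as
        y - sigma_obs * xi, so a sigma_obs move drags the latent path
        with it while the process density does the penalizing.
        """
        cp, cq, sig, theta_p, logp = self.unpack(phi)
        if not np.isfinite(logp):
            return -math.inf, None
        x = self.y - xi * np.array([sig[1], sig[3]])
        rp, rq = self.latent_regimes(x, theta_p)
        total = logp + self._proc_ll(x, rp, rq, cp, cq, sig)
        for k, s0 in enumerate(self.s0):
            total += -0.5 * ((x[0, k] - self.m0[k]) / s0) ** 2
        return total, x

    def innovations(self, phi: np.ndarray, x: np.ndarray) -> np.ndarray:
        cp, cq, sig, theta_p, _ = self.unpack(phi)
        return _kalman.eta_from_x(
            x, self.st, self.nao, cp, cq, sig,
            theta_p if theta_p is not None else 0.0, self.pred_threshold,
            self.theta_prey if self.theta_prey is not None else 0.0,
            self.prey_threshold, self.prey_same_year,
        )

    def log_posterior(
        self, phi: np.ndarray, latent_pred: np.ndarray, latent_prey: np.ndarray
    ) -> float:
        """Exact joint log-posterior density (up to a constant) at
        parameters ``phi`` (unconstrained) and latent trajectories.

        Assembled as prior + initial-state prior + process log-density
        (regimes from the latent prey path) + observation log-density.
        """
        cp, cq, sig, theta_p, logp = self.unpack(phi)
        if not np.isfinite(logp):
            return -math.inf
        x = np.column_stack([latent_pred, latent_prey])
        rp, rq = _kalman.regimes_from_series(
            x[:, 0], x[:, 1], theta_p if self.pred_threshold else None,
            self.theta_prey, self.prey_same_year,
        )
        proc = _kalman.process_loglik_latent(
            x, self.st, self.nao, rp, rq, cp, cq, sig, self.prey_same_year
        )
        total = logp + proc
        for k, s0 in enumerate(self.s0):
            total += -0.5 * (
                _LOG_2PI + 2.0 * math.log(s0) + ((x[0, k] - self.m0[k]) / s0) ** 2
            )
        for k in (0, 1):
            so = sig[2 * k + 1]
            resid = self.y[:, k] - x[:, k]
            total += float(
                np.sum(-0.5 * (_LOG_2PI + 2.0 * math.log(so) + (resid / so) ** 2))
            )
        return total


def build_joint_model(
    dataset: AlignedDataset,
    threshold_species: tuple[str, ...] | list[str] = (),
    theta: dict[str, float] | None = None,
    priors: PriorConfig | None = None,
    sample_theta: bool = False,
) -> JointModel:
    """Assemble the joint two-species posterior.

    ``threshold_species`` lists the species (usually just
    ``"predator"``) whose equation switches regimes; ``theta`` gives the
    fixed threshold per such species (profile-then-fit default), unless
    ``sample_theta`` puts a uniform prior over the candidate-grid range.
    """
    return JointModel(
        dataset=dataset,
        threshold_species=tuple(threshold_species),
        theta=dict(theta or {}),
        priors=priors or PriorConfig(),
        sample_theta=sample_theta,
    )


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, indexed (chain, draw)."""

    params: dict[str, np.ndarray]
    latent_pred: np.ndarray  # (chains, draws, T)
    latent_prey: np.ndarray
    config: MCMCConfig
    model: JointModel = field(repr=False)
    accept_rate: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (parameter, chain, iteration, value)."""
        rows = []
        for name, arr in self.params.items():
            nc, nd = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(nc), nd),
                        "iteration": np.tile(np.arange(nd), nc),
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter median, %>0, central 95% interval and R-hat."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if ((t["pct_gt0"] < 0) | (t["pct_gt0"] > 100)).any():
            raise ValueError("%>0 outside [0, 100]")
        bad = (t["median"] < t["ci_lo"]) | (t["median"] > t["ci_hi"])
        if bad.any():
            raise ValueError("median outside its 95% interval")

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


# -- sampler ------------------------------------------------------------


def _chol(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(d))
        except np.linalg.LinAlgError:
            continue
    return np.linalg.cholesky(np.diag(np.clip(np.diag(cov), 1e-8, None)))


def _run_chain(model: JointModel, mcmc: MCMCConfig, phi0, cov_sig0, rng):
    """One MCMC chain: FFBS-within-Gibbs.

    Each iteration performs
      1. a Metropolised exact-smoother (FFBS) refresh of the latent
         trajectories, with regimes pinned to the current latent prey
         path so the acceptance probability is 1 absent regime flips;
      2. an adaptive random-walk move of the variance block (log
         observation sds, log variance ratios, plus theta when sampled)
         conditional on the latent states;
      3. an exact Gaussian (conjugate) draw of all regression
         coefficients given the latent states.
    Adaptation stops at the end of burn-in.
    """
    burn = mcmc.burn_in
    total = mcmc.iterations
    n_ret = mcmc.n_retained
    T = model.T
    sl_sig = model.sigma_slice

    phi = phi0.copy()
    val, state = model.marginal_log_posterior(phi)
    if not np.isfinite(val):
        raise RuntimeError("invalid starting point for MCMC chain")
    cp, cq, sig, rp, rq, mf, Pf = state
    x, _ = _kalman.ffbs(
        mf, Pf, model.st, model.nao, rp, rq, cp, cq, sig,
        model.prey_same_year, rng.standard_normal((T, 2)),
    )

    # per-species variance sub-blocks (theta joins the predator block)
    idx_pred = list(range(sl_sig.start, sl_sig.start + 2))
    idx_prey = list(range(sl_sig.start + 2, sl_sig.start + 4))
    if model.sample_theta:
        idx_pred.append(sl_sig.stop - 1)
    blocks = [np.array(idx_pred), np.array(idx_prey)]
    n_sub = 2  # centered variance sub-updates per iteration
    log_scales = [math.log(1.0) for _ in blocks]
    Ls = [np.linalg.cholesky(0.05 * np.eye(len(b))) for b in blocks]
    hists = [np.empty((2 * burn * n_sub, len(b))) for b in blocks]
    adapt_counts = [0 for _ in blocks]
    # interweaved (non-centered) variance proposals, separate adaptation
    log_scales_nc = [math.log(1.0) for _ in blocks]
    Ls_nc = [np.linalg.cholesky(0.05 * np.eye(len(b))) for b in blocks]
    hists_nc = [np.empty((2 * burn, len(b))) for b in blocks]
    adapt_counts_nc = [0 for _ in blocks]
    log_scales_oc = [math.log(1.0) for _ in blocks]
    Ls_oc = [np.linalg.cholesky(0.05 * np.eye(len(b))) for b in blocks]
    hists_oc = [np.empty((2 * burn, len(b))) for b in blocks]
    adapt_counts_oc = [0 for _ in blocks]
    # marginal variance moves: proposal shaped by the marginal posterior
    # spread estimated from the burn-in history, with per-variant scale
    # adaptation (the acceptance of these moves is limited by how far
    # the transported/redrawn path can jump, not by the classic 2-dim
    # random-walk geometry)
    hist_marg = np.empty((burn, sl_sig.stop - sl_sig.start))
    Ls_marg = [np.linalg.cholesky(0.05 * np.eye(len(b))) for b in blocks]
    marg_scales = {"pred": math.log(1.2), "white": math.log(0.7), "flip": math.log(0.7)}

    out = {name: np.empty(n_ret) for name in model.param_names}
    lat_u = np.empty((n_ret, T))
    lat_v = np.empty((n_ret, T))
    accepts = 0
    kept = 0
    exact_gibbs = not model.prey_threshold
    for i in range(total):
        adapting = i < burn
        for _cycle in range(2):
            # --- 1. latent refresh -----------------------------------------
            if exact_gibbs:
                cp, cq, sig, theta_p, _ = model.unpack(phi)
                rp, _ = model.latent_regimes(x, theta_p)
                x[:, 0], _ = _kalman.predator_ffbs(
                    model.y[:, 0], x[:, 1], model.st, model.nao, rp, cp, cq, sig,
                    model.m0[0], model.s0[0], model.prey_same_year,
                    rng.standard_normal(T),
                )
                # global prey redraw first (high acceptance at short T),
                # then windowed prey-path redraws: conditional FFBS per window
                # with pinned regimes and exact flip corrections; window
                # offsets are randomized so block edges move around
                rp = model.prey_window_update(cp, cq, sig, theta_p, x, rp, 0, T - 1, rng)
                Lw = 16
                for _pass in range(2):
                    off = int(rng.integers(1, Lw + 1))
                    edges = [0]
                    g = off
                    while g < T:
                        edges.append(g)
                        g += Lw
                    edges.append(T)
                    for w in range(len(edges) - 1):
                        s_w, e_w = edges[w], edges[w + 1] - 1
                        if e_w >= s_w:
                            rp = model.prey_window_update(
                                cp, cq, sig, theta_p, x, rp, s_w, e_w, rng
                            )
                for _sweep in range(4):
                    _kalman.prey_gibbs_sweep(
                        x[:, 1], x[:, 0], model.y[:, 1], model.st, model.nao, cp, cq,
                        sig, theta_p if model.pred_threshold else 0.0,
                        model.pred_threshold, model.m0[1], model.s0[1],
                        model.prey_same_year, rng.random((T, 2)), _sweep % 2 == 1,
                    )
            else:
                x, _moved = model.x_update(phi, x, rng)

            # --- 2. variance sub-blocks, conditional on latent -------------
            sig_target = model.sigma_logpost(phi, x)
            for _rep in range(n_sub):
                for b, idx in enumerate(blocks):
                    db = len(idx)
                    phi_new = phi.copy()
                    phi_new[idx] = phi[idx] + math.exp(log_scales[b]) * (
                        Ls[b] @ rng.standard_normal(db)
                    )
                    sig_target_new = model.sigma_logpost(phi_new, x)
                    accept = math.log(rng.random()) < sig_target_new - sig_target
                    if accept:
                        phi = phi_new
                        sig_target = sig_target_new
                        if not adapting:
                            accepts += 1
                    if adapting:
                        j = adapt_counts[b]
                        hists[b][j] = phi[idx]
                        adapt_counts[b] += 1
                        gamma = 1.0 / math.sqrt(j + 20.0)
                        log_scales[b] += gamma * ((1.0 if accept else 0.0) - 0.35)
                        if j >= 99 and (j + 1) % 100 == 0:
                            emp = np.cov(hists[b][max(0, j - 999) : j + 1].T)
                            Ls[b] = _chol(np.atleast_2d(emp) + 1e-9 * np.eye(db))

            # --- 2b. interweaved non-centered variance update --------------
            # Re-express the latent path as standardized innovations and
            # move the variance block with them held fixed: the path is
            # rebuilt under the proposal, breaking the sigma-path coupling.
            eta = model.innovations(phi, x)
            x0 = x[0].copy()
            cur_val, _ = model.noncentered_logpost(phi, x0, eta)
            for b, idx in enumerate(blocks):
                db = len(idx)
                phi_new = phi.copy()
                phi_new[idx] = phi[idx] + math.exp(log_scales_nc[b]) * (
                    Ls_nc[b] @ rng.standard_normal(db)
                )
                new_val, x_new = model.noncentered_logpost(phi_new, x0, eta)
                accept = np.isfinite(new_val) and (
                    math.log(rng.random()) < new_val - cur_val
                )
                if accept:
                    phi, cur_val, x = phi_new, new_val, x_new
                if adapting:
                    j = adapt_counts_nc[b]
                    hists_nc[b][j] = phi[idx]
                    adapt_counts_nc[b] += 1
                    gamma = 1.0 / math.sqrt(j + 20.0)
                    log_scales_nc[b] += gamma * ((1.0 if accept else 0.0) - 0.35)
                    if j >= 99 and (j + 1) % 100 == 0:
                        emp = np.cov(hists_nc[b][max(0, j - 999) : j + 1].T)
                        Ls_nc[b] = _chol(np.atleast_2d(emp) + 1e-9 * np.eye(db))

            # --- 2c. interweaved observation-side variance update ----------
            _, _, sig_cur, _, _ = model.unpack(phi)
            xi = (model.y - x) / np.array([sig_cur[1], sig_cur[3]])
            cur_val, _ = model.obs_noncentered_logpost(phi, xi)
            for b, idx in enumerate(blocks):
                db = len(idx)
                phi_new = phi.copy()
                phi_new[idx] = phi[idx] + math.exp(log_scales_oc[b]) * (
                    Ls_oc[b] @ rng.standard_normal(db)
                )
                new_val, x_new = model.obs_noncentered_logpost(phi_new, xi)
                accept = np.isfinite(new_val) and (
                    math.log(rng.random()) < new_val - cur_val
                )
                if accept:
                    phi, cur_val, x = phi_new, new_val, x_new
                if adapting:
                    j = adapt_counts_oc[b]
                    hists_oc[b][j] = phi[idx]
                    adapt_counts_oc[b] += 1
                    gamma = 1.0 / math.sqrt(j + 20.0)
                    log_scales_oc[b] += gamma * ((1.0 if accept else 0.0) - 0.35)
                    if j >= 99 and (j + 1) % 100 == 0:
                        emp = np.cov(hists_oc[b][max(0, j - 999) : j + 1].T)
                        Ls_oc[b] = _chol(np.atleast_2d(emp) + 1e-9 * np.eye(db))

            # --- 2d. marginal variance moves with joint path redraw --------
            if adapting:
                hist_marg[i] = phi[sl_sig]
                if i >= 199 and (i + 1) % 200 == 0:
                    window = hist_marg[max(0, i - 999) : i + 1]
                    for b, idx in enumerate(blocks):
                        sub = window[:, [k - sl_sig.start for k in idx]]
                        emp = np.atleast_2d(np.cov(sub.T)) + 1e-9 * np.eye(len(idx))
                        Ls_marg[b] = _chol(emp)
            if exact_gibbs and not model.sample_theta:
                cp, cq, sig, theta_p, _ = model.unpack(phi)
                rp, _ = model.latent_regimes(x, theta_p)
                for _rep in range(8):
                    for b, idx in enumerate(blocks):
                        db = len(idx)
                        if b == 0:
                            variant = "pred"
                        else:
                            variant = "white" if _rep % 2 == 0 else "flip"
                        step = math.exp(marg_scales[variant]) * (
                            Ls_marg[b] @ rng.standard_normal(db)
                        )
                        phi_new = phi.copy()
                        phi_new[idx] = phi_new[idx] + step
                        if variant == "pred":
                            phi, _am = model.pred_sigma_marginal(
                                phi, phi_new, x, rp, rng
                            )
                        elif variant == "white":
                            phi, _am = model.prey_sigma_marginal_white(
                                phi, phi_new, x, rp, theta_p, rng
                            )
                        else:
                            phi, rp, _am = model.prey_sigma_marginal(
                                phi, phi_new, x, rp, theta_p, rng
                            )
            else:
                for _rep in range(6):
                    for b, idx in enumerate(blocks):
                        db = len(idx)
                        step = (2.8 / math.sqrt(db)) * (
                            Ls_marg[b] @ rng.standard_normal(db)
                        )
                        phi, x, acc_m = model.sigma_marginal_update(
                            phi, x, idx, step, rng, truncated=_rep % 2 == 0
                        )

            # --- 3. conjugate coefficient draw given latent ----------------
            phi = model.gibbs_coefficients(phi, x, rng)

        if not adapting:
            j = i - burn
            if (j + 1) % mcmc.thin == 0 and kept < n_ret:
                for k, name in enumerate(model.param_names):
                    out[name][kept] = phi[k]
                lat_u[kept] = x[:, 0]
                lat_v[kept] = x[:, 1]
                kept += 1
    acc_rate = accepts / max((total - burn) * n_sub * len(blocks), 1)
    return out, lat_u, lat_v, acc_rate


def _to_natural(model: JointModel, raw: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Transform sampled columns to the reporting scale and derive
    sigma_proc from (sigma_obs, ratio)."""
    out: dict[str, np.ndarray] = {}
    for name, arr in raw.items():
        if name.startswith("sigma_obs") or name.startswith("ratio"):
            out[name] = np.exp(arr)
        else:
            out[name] = arr
    for sp in ("pred", "prey"):
        out[f"sigma_proc_{sp}"] = out[f"sigma_obs_{sp}"] * np.sqrt(out[f"ratio_{sp}"])
    return out


def fit(model: JointModel, mcmc: MCMCConfig) -> PosteriorDraws:
    """Sample the joint posterior; reproducible for a fixed seed.

    Each chain starts from a jittered least-squares point; burn-in
    adapts the variance-block random walk, which is frozen for the
    retained phase so those draws come from a fixed, valid MH kernel.
    """
    if mcmc.seed is None:
        raise ValueError("MCMCConfig.seed must be set for a reproducible fit")
    phi_start = model.pack_start()
    sl = model.sigma_slice
    d_sig = sl.stop - sl.start
    cov_sig0 = 0.05 * np.eye(d_sig)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    raw = {name: np.empty((mcmc.chains, mcmc.n_retained)) for name in model.param_names}
    lat_u = np.empty((mcmc.chains, mcmc.n_retained, model.T))
    lat_v = np.empty((mcmc.chains, mcmc.n_retained, model.T))
    acc = np.empty(mcmc.chains)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        phi0 = phi_start.copy()
        phi0[sl] = phi0[sl] + 0.2 * rng.standard_normal(d_sig)
        val, _ = model.marginal_log_posterior(phi0)
        if not np.isfinite(val):
            phi0 = phi_start
        out, lu, lv, a = _run_chain(model, mcmc, phi0, cov_sig0, rng)
        for name in raw:
            raw[name][c] = out[name]
        lat_u[c] = lu
        lat_v[c] = lv
        acc[c] = a
    return PosteriorDraws(
        params=_to_natural(model, raw),
        latent_pred=lat_u,
        latent_prey=lat_v,
        config=mcmc,
        model=model,
        accept_rate=acc,
    )


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Median, %>0 (strict), central 95% interval and split R-hat."""
    from .diagnostics import gelman_rubin

    if draws.n_draws == 0:
        raise ValueError("no retained draws to summarize")
    rows = {}
    for name, arr in draws.params.items():
        flat = arr.reshape(-1)
        rows[name] = {
            "median": float(np.median(flat)),
            "pct_gt0": 100.0 * float(np.mean(flat > 0)),
            "ci_lo": float(np.percentile(flat, 2.5)),
            "ci_hi": float(np.percentile(flat, 97.5)),
            "rhat": gelman_rubin(arr),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "parameter"
    return PosteriorSummary(table=table)


def sensitivity_ratio_prior(
    dataset: AlignedDataset,
    threshold_species: tuple[str, ...] = (),
    theta: dict[str, float] | None = None,
    centers: tuple[float, ...] = (0.5, 1.0, 2.0),
    mcmc: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
) -> pd.DataFrame:
    """Refit with the ratio prior centred at each value; medians side by side.

    The ratio prior keeps its sd of 0.5 at every centre.
    """
    base = priors or PriorConfig()
    mcmc = mcmc or reduced_mcmc(seed=0)
    cols = {}
    for center in centers:
        pri = replace(base, ratio_mean=float(center))
        model = build_joint_model(
            dataset, threshold_species=threshold_species, theta=theta, priors=pri
        )
        summ = summarize(fit(model, mcmc))
        cols[f"center_{center:g}"] = summ.table["median"]
    return pd.DataFrame(cols)


def process_error_correlation(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior of the correlation between the two species' realized
    process errors, computed per retained draw from the latent paths."""
    model = draws.model
    T = model.T
    if T - 1 < 3:
        raise ValueError("need at least 3 transition years")
    names = model.param_names
    corrs = []
    for c in range(draws.n_chains):
        for j in range(draws.n_draws):
            phi = np.array(
                [
                    math.log(draws.params[n][c, j])
                    if n.startswith(("sigma_obs", "ratio"))
                    else draws.params[n][c, j]
                    for n in names
                ]
            )
            cp, cq, sig, theta_p, _ = model.unpack(phi)
            x = np.column_stack([draws.latent_pred[c, j], draws.latent_prey[c, j]])
            rp, rq = _kalman.regimes_from_series(
                x[:, 0], x[:, 1], theta_p if model.pred_threshold else None,
                model.theta_prey, model.prey_same_year,
            )
            eu, ev = _residuals(model, x, rp, rq, cp, cq)
            if np.std(eu) == 0 or np.std(ev) == 0:
                raise ValueError("constant process residuals")
            corrs.append(float(np.corrcoef(eu, ev)[0, 1]))
    corrs = np.asarray(corrs)
    return pd.DataFrame(
        {
            "median": [float(np.median(corrs))],
            "ci_lo": [float(np.percentile(corrs, 2.5))],
            "ci_hi": [float(np.percentile(corrs, 97.5))],
        },
        index=["proc_error_corr"],
    )


def _residuals(model: JointModel, x, rp, rq, cp, cq):
    T = model.T
    t = np.arange(1, T)
    a0u = np.where(rp[t] == 0, cp[0], cp[5])
    acu = np.where(rp[t] == 0, cp[2], cp[6])
    mu_u = (
        a0u + cp[1] * x[t - 1, 0] + acu * x[t - 1, 1]
        + cp[3] * model.st[t - 1] + cp[4] * model.nao[t - 1]
    )
    eu = x[t, 0] - mu_u
    a0v = np.where(rq[t] == 0, cq[0], cq[5])
    acv = np.where(rq[t] == 0, cq[2], cq[6])
    partner = x[t, 0] if model.prey_same_year else x[t - 1, 0]
    mu_v = (
        a0v + cq[1] * x[t - 1, 1] + acv * partner
        + cq[3] * model.st[t - 1] + cq[4] * model.nao[t - 1]
    )
    ev = x[t, 1] - mu_v
    return eu, ev
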