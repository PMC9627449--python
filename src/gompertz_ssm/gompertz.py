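"""Linear and threshold Gompertz process equations, log-densities, simulation.

The Gompertz model is linear on the log-abundance scale: for species *i*
with partner species *j*,

    ln N[i,t] = a0 + a_self * ln N[i,t-1] + a_cross * ln N[j,t-lag]
                + a_st * ST[t-1] + a_nao * NAO[t-1] + eps[i,t],

with eps ~ Normal(0, sigma_proc^2).  The threshold variant switches the
intercept and the partner coefficient between two regimes depending on
whether the partner's lagged log abundance is below (``a0``, ``a_cross``)
or at/above (``b0``, ``b_cross``) a threshold ``theta``; the density
dependence and covariate coefficients are shared across regimes.
Observations are log abundances with Gaussian error sd ``sigma_obs``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .timeseries_io import AnnualSeries, LagConvention

__all__ = [
    "ThresholdBlock",
    "GompertzParams",
    "LatentTrajectory",
    "process_mean_linear",
    "process_mean_threshold",
    "process_loglik",
    "obs_loglik",
    "simulate_pair",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ThresholdBlock:
    """Upper-regime intercept/partner coefficient and the threshold level.

    ``theta`` is on the partner's log-abundance scale (log 1e9
    individuals).  A partner value exactly at ``theta`` falls in the
    upper regime.
    """

    b0: float
    b_cross: float
    theta: float


@dataclass(frozen=True)
class GompertzParams:
    """Process and observation parameters for one species."""

    a0: float = 0.0
    a_self: float = 0.0
    a_cross: float = 0.0
    a_st: float = 0.0
    a_nao: float = 0.0
    sigma_proc: float = 0.0
    sigma_obs: float = 0.0
    threshold: Optional[ThresholdBlock] = None

    def __post_init__(self) -> None:
        if self.sigma_proc < 0 or self.sigma_obs < 0:
            raise ValueError("error standard deviations must be >= 0")

    @property
    def is_threshold(self) -> bool:
        return self.threshold is not None

    def collapse_threshold(self) -> "GompertzParams":
        """Make the two regimes identical (b0=a0, b_cross=a_cross).

        The result is still threshold-typed but dynamically linear; used
        for null scenarios in relevance calibration.
        """
        if self.threshold is None:
            return self
        return replace(
            self,
            threshold=ThresholdBlock(
                b0=self.a0, b_cross=self.a_cross, theta=self.threshold.theta
            ),
        )


@dataclass(frozen=True)
class LatentTrajectory:
    """Latent log abundances ln N over the aligned year window."""

    years: np.ndarray
    ln_n: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        ln_n = np.asarray(self.ln_n, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "ln_n", ln_n)
        if len(years) != len(ln_n):
            raise ValueError("years and ln_n must have equal length")

    def __len__(self) -> int:
        return len(self.years)


def process_mean_linear(
    p: GompertzParams,
    ln_self_prev: float,
    ln_partner_lagged: float,
    st_lagged: float = 0.0,
    nao_lagged: float = 0.0,
) -> float:
    """Deterministic part of the linear Gompertz process equation."""
    return (
        p.a0
        + p.a_self * ln_self_prev
        + p.a_cross * ln_partner_lagged
        + p.a_st * st_lagged
        + p.a_nao * nao_lagged
    )


def process_mean_threshold(
    p: GompertzParams,
    ln_self_prev: float,
    ln_partner_lagged: float,
    st_lagged: float = 0.0,
    nao_lagged: float = 0.0,
) -> float:
    """Two-regime process mean; regime chosen by the lagged partner value."""
    if p.threshold is None:
        raise ValueError("threshold block required for the two-regime mean")
    if ln_partner_lagged < p.threshold.theta:
        a0, a_cross = p.a0, p.a_cross
    else:
        a0, a_cross = p.threshold.b0, p.threshold.b_cross
    return (
        a0
        + p.a_self * ln_self_prev
        + a_cross * ln_partner_lagged
        + p.a_st * st_lagged
        + p.a_nao * nao_lagged
    )


def _process_mean(p, ln_self_prev, ln_partner_lagged, st, nao) -> float:
    if p.threshold is not None:
        return process_mean_threshold(p, ln_self_prev, ln_partner_lagged, st, nao)
    return process_mean_linear(p, ln_self_prev, ln_partner_lagged, st, nao)


def _gauss_logpdf(resid: float, sd: float) -> float:
    # sd == 0 is a documented sentinel: point mass at zero residual.
    if sd == 0.0:
        return math.inf if resid == 0.0 else -math.inf
    return -0.5 * (_LOG_2PI + 2.0 * math.log(sd) + (resid / sd) ** 2)


def process_loglik(
    p: GompertzParams,
    self_traj: LatentTrajectory,
    partner_traj: LatentTrajectory,
    st: np.ndarray | None = None,
    nao: np.ndarray | None = None,
    lag: LagConvention | None = None,
    partner_lag: int | None = None,
) -> float:
    """Gaussian log-likelihood of the process equation along a trajectory.

    The first year is the initial condition and contributes no
    transition density.  ``partner_lag`` (0 or 1) gives the lag of the
    partner trajectory entering each transition; if omitted it is taken
    from ``lag.predator_prey_lag`` (default 1).
    """
    T = len(self_traj)
    if len(partner_traj) != T:
        raise ValueError("trajectories must be aligned")
    if partner_lag is None:
        partner_lag = (lag or LagConvention()).predator_prey_lag
    st = np.zeros(T) if st is None else np.asarray(st, dtype=float)
    nao = np.zeros(T) if nao is None else np.asarray(nao, dtype=float)
    x = self_traj.ln_n
    z = partner_traj.ln_n
    total = 0.0
    for t in range(1, T):
        partner_val = z[t - partner_lag]
        mu = _process_mean(p, x[t - 1], partner_val, st[t - 1], nao[t - 1])
        total += _gauss_logpdf(x[t] - mu, p.sigma_proc)
    return total


def obs_loglik(p: GompertzParams, traj: LatentTrajectory, obs: AnnualSeries) -> float:
    """Log-likelihood of observed abundances around the latent states."""
    if len(obs) != len(traj) or np.any(obs.years != traj.years):
        raise ValueError("observation series and trajectory must share years")
    if np.any(obs.values <= 0):
        raise ValueError("observations must be strictly positive abundances")
    ln_obs = np.log(obs.values)
    total = 0.0
    for t in range(len(traj)):
        total += _gauss_logpdf(ln_obs[t] - traj.ln_n[t], p.sigma_obs)
    return total


def simulate_pair(
    p_predator: GompertzParams,
    p_prey: GompertzParams,
    init: tuple[float, float],
    st: np.ndarray | None = None,
    nao: np.ndarray | None = None,
    n_years: int = 39,
    seed: int | None = None,
    years: np.ndarray | None = None,
    lag: LagConvention | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate coupled predator-prey dynamics and noisy observations.

    Within each year the predator transitions first, using the prey at
    year-1 (which is also the threshold variable when the predator is
    threshold-typed); the prey then transitions using the predator's
    *same-year* latent state, reflecting the survey-timing convention.

    Returns ``(latent_predator, latent_prey, obs_predator, obs_prey)``
    where the latent objects are :class:`LatentTrajectory` and the
    observations are :class:`AnnualSeries` in 1e9-individual units.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years to simulate")
    lag = lag or LagConvention()
    if lag.predator_prey_lag == 0 and lag.prey_predator_lag == 0:
        raise ValueError(
            "lag convention creates a within-year cycle: at most one species "
            "may use the partner's same-year state"
        )
    predator_first = lag.predator_prey_lag == 1
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    st = np.zeros(n_years) if st is None else np.asarray(st, dtype=float)
    nao = np.zeros(n_years) if nao is None else np.asarray(nao, dtype=float)
    if years is None:
        years = np.arange(1981, 1981 + n_years)

    u = np.empty(n_years)  # predator ln N
    v = np.empty(n_years)  # prey ln N
    u[0], v[0] = init
    for t in range(1, n_years):
        def _step_pred():
            mu = _process_mean(
                p_predator,
                u[t - 1],
                v[t - lag.predator_prey_lag],
                st[t - 1],
                nao[t - 1],
            )
            u[t] = mu + p_predator.sigma_proc * rng.standard_normal()

        def _step_prey():
            mu = _process_mean(
                p_prey,
                v[t - 1],
                u[t - lag.prey_predator_lag],
                st[t - 1],
                nao[t - 1],
            )
            v[t] = mu + p_prey.sigma_proc * rng.standard_normal()

        if predator_first:
            _step_pred()
            _step_prey()
        else:
            _step_prey()
            _step_pred()

    obs_u = u + p_predator.sigma_obs * rng.standard_normal(n_years)
    obs_v = v + p_prey.sigma_obs * rng.standard_normal(n_years)

    lat_pred = LatentTrajectory(years=years, ln_n=u)
    lat_prey = LatentTrajectory(years=years, ln_n=v)
    obs_pred = AnnualSeries(
        years=years, values=np.exp(obs_u), label="predator", kind="abundance"
    )
    obs_prey = AnnualSeries(
        years=years, values=np.exp(obs_v), label="prey", kind="abundance"
    )
    return lat_pred, lat_prey, obs_pred, obs_prey
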