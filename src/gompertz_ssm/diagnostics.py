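"""Convergence diagnostics and posterior predictive checks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "PPCResult", "posterior_predictive"]


def gelman_rubin(chains: np.ndarray, split: bool = True) -> float:
    """Potential scale reduction factor R-hat for one parameter.

    ``chains`` has shape (n_chains, n_draws).  By default each chain is
    split in half (split-R-hat), which also flags within-chain trends
    and is stricter than the original diagnostic.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a (n_chains, n_draws) array")
    m, n = arr.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 10:
        raise ValueError("R-hat requires at least 10 draws per chain")
    if split:
        half = n // 2
        arr = np.vstack([arr[:, :half], arr[:, half : 2 * half]])
        m, n = arr.shape
    chain_means = arr.mean(axis=1)
    chain_vars = arr.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass(frozen=True)
class PPCResult:
    """Per-year posterior predictive summary for both species.

    ``table`` columns: year, species, lo, median, hi, observed, covered,
    regime (1 when the observed lagged prey abundance is at/above the
    threshold entering that year's predator equation, else 0).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if ((t["lo"] > t["median"]) | (t["median"] > t["hi"])).any():
            raise ValueError("predictive quantiles out of order")

    def coverage(self, species: str | None = None) -> float:
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        return float(t["covered"].mean())


def posterior_predictive(draws, seed: int | None = None) -> PPCResult:
    """Replicate observations from each retained draw and summarize.

    For every retained draw, a replicated observed log abundance is
    simulated around the drawn latent state with that draw's
    observation sd; per year we report the 2.5/50/97.5 percentiles of
    the replicates (equal-tailed 95% predictive band) and whether the
    actual observation falls inside.
    """
    if draws.n_draws == 0:
        raise ValueError("no retained draws for a posterior predictive check")
    model = draws.model
    rng = np.random.default_rng(seed)
    years = model.dataset.years
    rows = []
    for k, (species, lat) in enumerate(
        (("predator", draws.latent_pred), ("prey", draws.latent_prey))
    ):
        sd = draws.params[f"sigma_obs_{'pred' if k == 0 else 'prey'}"]
        flat_lat = lat.reshape(-1, model.T)
        flat_sd = sd.reshape(-1)[:, None]
        reps = flat_lat + flat_sd * rng.standard_normal(flat_lat.shape)
        lo, med, hi = np.percentile(reps, [2.5, 50.0, 97.5], axis=0)
        obs = model.y[:, k]
        regime = np.zeros(model.T, dtype=int)
        if model.pred_threshold and model.theta_pred is not None:
            regime[1:] = (model.y[:-1, 1] >= model.theta_pred).astype(int)
        for t in range(model.T):
            rows.append(
                {
                    "year": int(years[t]),
                    "species": species,
                    "lo": lo[t],
                    "median": med[t],
                    "hi": hi[t],
                    "observed": obs[t],
                    "covered": bool(lo[t] <= obs[t] <= hi[t]),
                    "regime": int(regime[t]),
                }
            )
    return PPCResult(table=pd.DataFrame(rows))


def plot_ppc(ppc: PPCResult, theta: float | None = None, path=None):
    """Log abundance vs year with 95% predictive bands and observations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 7), sharex=True)
    for ax, species in zip(axes, ("prey", "predator")):
        sub = ppc.table[ppc.table["species"] == species]
        ax.fill_between(sub["year"], sub["lo"], sub["hi"], alpha=0.3, label="95% PI")
        ax.plot(sub["year"], sub["median"], lw=1)
        upper = sub["regime"] == 1
        ax.plot(sub["year"][~upper], sub["observed"][~upper], "o", mfc="white")
        ax.plot(sub["year"][upper], sub["observed"][upper], "o")
        if theta is not None and species == "prey":
            ax.axhline(theta, ls=":", color="red")
        ax.set_ylabel(f"ln abundance ({species})")
        ax.legend(loc="best", fontsize=8)
    axes[-1].set_xlabel("year")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
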