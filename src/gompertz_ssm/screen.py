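"""Pairwise nonlinearity screening between explanatory variables.

The screen compares an additive linear regression of the response on all
explanatory variables against the same regression augmented with cross
terms of one variable pair (order 1 adds the product ``x_a * x_b``;
order ``o`` adds all terms ``x_a^i * x_b^j`` with ``i, j >= 1`` and
``i + j <= o + 1``).  The added terms are assessed with a nested-model
F-test on residual sums of squares.  A small p-value indicates the pair
interacts non-additively, which in the modelling pipeline motivates a
threshold (regime-switching) term.

The screen runs on observed log abundances, since it precedes any
state-space fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm

from .timeseries_io import AlignedDataset

__all__ = ["ScreenResult", "burmann_pair_test", "screen_all_pairs"]


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one pairwise interaction test."""

    pair: tuple[str, str]
    statistic: float
    p_value: float
    order: int
    n_obs: int
    df_num: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _check_predictor(name: str, x: np.ndarray) -> None:
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor {name!r} in interaction screen")


def _cross_terms(x_a: np.ndarray, x_b: np.ndarray, order: int) -> np.ndarray:
    cols = []
    for i in range(1, order + 1):
        for j in range(1, order + 1):
            if i + j <= order + 1:
                cols.append(x_a**i * x_b**j)
    return np.column_stack(cols)


def burmann_pair_test(
    response: np.ndarray,
    x_a: np.ndarray,
    x_b: np.ndarray,
    other_covariates: np.ndarray | None = None,
    order: int = 1,
    labels: tuple[str, str] = ("x_a", "x_b"),
    use_f_test: bool = True,
) -> ScreenResult:
    """Test whether ``x_a`` and ``x_b`` interact beyond additivity.

    Fits the additive baseline ``response ~ x_a + x_b + others`` and the
    augmented model with cross terms; returns the F statistic (or, with
    ``use_f_test=False``, the likelihood-ratio chi-square) and p-value
    for the added terms.  Symmetric in the ordering of the pair.
    """
    y = np.asarray(response, dtype=float)
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    n = len(y)
    if not (len(x_a) == len(x_b) == n):
        raise ValueError("response and predictors must have equal length")
    if n < 10:
        raise ValueError("need at least 10 observations for the screen")
    if order < 1:
        raise ValueError("expansion order must be >= 1")
    _check_predictor(labels[0], x_a)
    _check_predictor(labels[1], x_b)

    base_cols = [x_a, x_b]
    if other_covariates is not None and np.size(other_covariates):
        others = np.atleast_2d(np.asarray(other_covariates, dtype=float))
        if others.shape[0] == n and others.shape[1] != n:
            others = others.T
        for k, col in enumerate(others):
            _check_predictor(f"other[{k}]", col)
            base_cols.append(col)
    X0 = sm.add_constant(np.column_stack(base_cols))
    X1 = np.column_stack([X0, _cross_terms(x_a, x_b, order)])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("rank-deficient design in interaction screen")

    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, X1).fit()
    q = X1.shape[1] - X0.shape[1]
    if use_f_test:
        stat, p_value, _ = fit1.compare_f_test(fit0)
    else:
        stat, p_value, _ = fit1.compare_lr_test(fit0)
    return ScreenResult(
        pair=labels,
        statistic=float(stat),
        p_value=float(np.clip(p_value, 0.0, 1.0)),
        order=order,
        n_obs=n,
        df_num=q,
    )


def _species_design(dataset: AlignedDataset, species: str):
    """Response and explanatory variables of one species' process equation."""
    lag = dataset.lag
    u = dataset.predator.log_values
    v = dataset.prey.log_values
    st = dataset.covariate("st").values if _has(dataset, "st") else None
    nao = dataset.covariate("nao").values if _has(dataset, "nao") else None
    T = dataset.n_years
    t = np.arange(1, T)
    if species == "predator":
        y = u[t]
        own_prev = u[t - 1]
        partner = v[t - lag.predator_prey_lag]
        partner_name = "prey_lag%d" % lag.predator_prey_lag
        own_name = "predator_lag1"
    elif species == "prey":
        y = v[t]
        own_prev = v[t - 1]
        partner = u[t - lag.prey_predator_lag]
        partner_name = "predator_lag%d" % lag.prey_predator_lag
        own_name = "prey_lag1"
    else:
        raise ValueError("species must be 'predator' or 'prey'")
    variables = {own_name: own_prev, partner_name: partner}
    if st is not None:
        variables["st_lag1"] = st[t - lag.covariate_lag]
    if nao is not None:
        variables["nao_lag1"] = nao[t - lag.covariate_lag]
    return y, variables


def _has(dataset: AlignedDataset, label: str) -> bool:
    return any(c.label == label for c in dataset.covariates)


def screen_all_pairs(
    dataset: AlignedDataset,
    species: str,
    order: int = 1,
    holm: bool = False,
) -> list[ScreenResult]:
    """Run the pair test over every unordered pair of explanatory variables.

    With the full covariate set (lagged self, lagged partner, ST, NAO)
    this yields 6 results.  ``holm=True`` applies a Holm step-down
    adjustment to the p-values (off by default; raw p-values mirror the
    reporting convention of the screening literature).
    """
    y, variables = _species_design(dataset, species)
    names = list(variables)
    results = []
    for na, nb in combinations(names, 2):
        others = [variables[k] for k in names if k not in (na, nb)]
        res = burmann_pair_test(
            y,
            variables[na],
            variables[nb],
            other_covariates=np.column_stack(others) if others else None,
            order=order,
            labels=(na, nb),
        )
        results.append(res)
    if holm:
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([r.p_value for r in results], method="holm")
        results = [
            ScreenResult(r.pair, r.statistic, float(p), r.order, r.n_obs, r.df_num)
            for r, p in zip(results, adj)
        ]
    return results
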