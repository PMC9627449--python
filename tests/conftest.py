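"""Shared fixtures.

The expensive Bayesian fits (the n=300 parameter-recovery fit and the
20-replicate coverage study at n=39) are session-scoped so the recovery,
convergence and predictive-check assertions all reuse one computation.
"""

import numpy as np
import pytest

from gompertz_ssm.bayes import build_joint_model, fit, reduced_mcmc, summarize
from gompertz_ssm.synthetic import ScenarioConfig, generate

TRUE_PARAMS = {
    "a_pred_0": 0.94,
    "a_pred_self": 0.84,
    "a_pred_prey": 0.03,
    "a_pred_st": 0.06,
    "a_pred_nao": 0.05,
    "b_pred_0": -1.85,
    "b_pred_prey": 0.52,
    "a_prey_0": 5.74,
    "a_prey_self": 0.56,
    "a_prey_pred": -0.49,
    "a_prey_st": 0.17,
    "a_prey_nao": -0.01,
    "sigma_obs_pred": 0.3,
    "sigma_proc_pred": 0.3,
    "sigma_obs_prey": 0.3,
    "sigma_proc_prey": 0.3,
}

# slope/covariate coefficients: the parameters the interaction analysis is
# about; the regime intercepts are intrinsically wide (see docs/methods.md)
COEFFICIENTS = [
    "a_pred_self",
    "a_pred_prey",
    "a_pred_st",
    "a_pred_nao",
    "b_pred_prey",
    "a_prey_self",
    "a_prey_pred",
    "a_prey_st",
    "a_prey_nao",
]


@pytest.fixture(scope="session")
def default_dataset():
    dataset, truth = generate(ScenarioConfig(seed=3))
    return dataset, truth


@pytest.fixture(scope="session")
def recovery_fit():
    """Joint fit of one n=300 dataset simulated at the reference
    parameter values, at the desk-scale MCMC settings."""
    dataset, truth = generate(ScenarioConfig(seed=11, n_years=300))
    model = build_joint_model(
        dataset, threshold_species=("predator",), theta={"predator": 5.34}
    )
    draws = fit(model, reduced_mcmc(seed=42))
    return model, draws, summarize(draws), truth


@pytest.fixture(scope="session")
def coverage_study():
    """95% credible-interval coverage over 20 replicate n=39 fits."""
    hits = 0
    total = 0
    for rep in range(20):
        dataset, truth = generate(ScenarioConfig(seed=100 + rep))
        model = build_joint_model(
            dataset, threshold_species=("predator",), theta={"predator": 5.34}
        )
        summ = summarize(fit(model, reduced_mcmc(seed=200 + rep)))
        for name, true_val in TRUE_PARAMS.items():
            row = summ.table.loc[name]
            hits += bool(row["ci_lo"] <= true_val <= row["ci_hi"])
            total += 1
    return hits, total
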