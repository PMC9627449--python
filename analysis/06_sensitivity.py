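"""Sensitivity of the fit to the variance-ratio prior centre.

Refits the joint model with the process/observation variance-ratio
prior centred at 0.5, 1 and 2 (sd 0.5 throughout) and tabulates the
posterior medians side by side; materially unchanged medians indicate
the data, not the centre, drive the inference.
"""

import pathlib

from gompertz_ssm.bayes import MCMCConfig, sensitivity_ratio_prior
from gompertz_ssm.synthetic import ScenarioConfig, generate

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"

def main():
    dataset, _ = generate(ScenarioConfig(seed=3))
    table = sensitivity_ratio_prior(
        dataset, threshold_species=("predator",), theta={"predator": 5.34},
        centers=(0.5, 1.0, 2.0),
        mcmc=MCMCConfig(chains=2, iterations=1500, burn_in=750, thin=1, seed=60),
    )
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "sensitivity_ratio_prior.csv")
    print(table.round(3).to_string())
    coef = [r for r in table.index
            if r.startswith(("a_", "b_")) and not r.endswith("_0")]
    spread = (table.loc[coef].max(axis=1) - table.loc[coef].min(axis=1))
    print(f"\nmax slope-median spread across centres: {spread.max():.3f}"
          " (regime intercepts are intrinsically wide at n=39)")

if __name__ == "__main__":
    main()
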