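# Full-pipeline configuration for `gompertz-ssm analyze examples/config.yaml`.
# `simulate` writes the dataset these paths point at; with real survey
# files, set the paths (and scale factors, e.g. 1e9 for files holding
# individuals) and skip the simulate step.
seed: 1
output_dir: results/run1

simulate:
  n_years: 39

data:
  predator: results/run1/predator.csv
  prey: results/run1/prey.csv
  # predator_scale: 1.0e9   # divide raw file values to reach 1e9-individual units
  covariates:
    - {path: results/run1/st.csv, label: st}
    - {path: results/run1/nao.csv, label: nao}

lag:
  predator_prey_lag: 1   # predator uses prey at year-1 (threshold variable)
  prey_predator_lag: 0   # prey uses the predator's same-year state
  covariate_lag: 1

screen:
  order: 1
  alpha: 0.05

threshold:
  criterion: bootstrap
  n_boot: 200

mcmc:                    # desk-scale; set paper_settings: true for 4x50000
  chains: 4
  iterations: 2000
  burn_in: 1000
  thin: 1
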