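# Simulation scenario: every generative quantity in one place.
# Load with `SimulationScenario.from_yaml` or pass to
# `virtualcontrols simulate-cohort / simulate --scenario`.

p: 3                      # number of continuous covariates (standard normal)
beta: [0.5, 0.4, 0.3]     # true outcome coefficients; Var(x.beta) = 0.5 here
intercept: 0.0
sigma: 0.5774             # residual s.d.; with beta above, true R^2 = 0.60
tau: 0.5                  # true treatment effect (log-odds shift if binary)
gamma: 0.0                # hidden-confounder effect on the outcome
selection: none           # none | observed | hidden (self-selection mode)
selection_strength: 1.0   # log-odds slope of opting in
selection_offset: 0.0     # log-odds of baseline opt-in
preference: 0.5           # fraction preferring treatment (RCT simulation)
demoralization: 0.0       # outcome penalty for assignment against preference
n_train: 500              # untreated training-cohort size
n_treated: 100            # single-arm cohort size
n_rct_per_arm: 100        # randomized-arm size
outcome_scale: continuous # continuous | binary
rho: 0.0                  # exchangeable correlation among continuous covariates
binary_prevalence: []     # optional binary covariates: prevalences ...
binary_beta: []           # ... and their coefficients
seed: 0                   # default stream when no seed is passed explicitly
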