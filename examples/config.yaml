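# Example run-all configuration (see `choicetraj run-all --config ...`).
# Omitted keys fall back to the defaults shown here.
seed: 0
n_participants: 198
outdir: choicetraj_output
attrition_mechanism: MCAR_dropout   # or MAR_dropout
simulate_sessions: true             # estimate covariates from adaptive tasks
session_trials: null                # null = battery defaults (30, 40 for gambles)
trajectory_step: 0.1                # years, for exported trajectory tables
verbosity: 1
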