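# Default study configuration: the five-day two-group design.
# Any key omitted here keeps the package default.
observer:
  wf_start: 0.20        # baseline internal Weber fraction
  wf_asymptote: 0.13    # post-learning asymptote (improving conditions)
  tau_sessions: 1.5     # learning time constant, sessions
  lapse_rate: 0.02
  jitter_cv: 0.10       # inter-individual lognormal jitter
staircase:
  trials_per_block: 60
  initial_delta_fraction: 0.20
  coarse_step_fraction: 0.10
  fine_step_fraction: 0.05
  step_change_after_reversal: 3
schedule:
  n_ei: 11
  n_fi: 12
  training_blocks_per_session: 12
  n_training_sessions: 4
  practice_trials: 10
analysis:
  mad_center: participant-median   # or group-mean
  n_mads: 3.0
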