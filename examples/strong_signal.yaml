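# Strong-signal synthetic cohort: 10 suicide-related CUIs mentioned in 30%
# of positive-patient notes vs 2% of negative-patient notes, ~9 notes per
# patient. Run with:
#   suicidality-pipeline all --config examples/strong_signal.yaml --out rundir/
seed: 3
rundir: rundir
simulate:
  n_patients: 120
  prevalence: 0.37
  notes_mu: 2.0
  notes_sigma: 0.6
  notes_range: [1, 40]
  signal_cuis:
    - [C0424000, 0.30, 0.02]
    - [C1000001, 0.30, 0.02]
    - [C1000002, 0.30, 0.02]
    - [C1000003, 0.30, 0.02]
    - [C1000004, 0.30, 0.02]
    - [C1000005, 0.30, 0.02]
    - [C1000006, 0.30, 0.02]
    - [C1000007, 0.30, 0.02]
    - [C1000008, 0.30, 0.02]
    - [C1000009, 0.30, 0.02]
parameters:
  n_trees: 300
  sens_floor: 0.70
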