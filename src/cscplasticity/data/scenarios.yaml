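# Packaged synthetic-data scenarios.
#
# These parameter sets are fixtures that emulate the qualitative study
# conditions: a pure biomarker-negative starting population whose
# positive fraction rises slowly to a small non-zero equilibrium under
# normoxia, and, under hypoxia, suppressed growth with a ten-fold jump
# in the dedifferentiation rate at day 3.
normoxia:
  params:
    alpha_S: 0.8
    delta_S: 0.1
    alpha_D: 0.9
    delta_D: 0.1
    k_SD: 0.1
    k_DS: [[0.0, 0.002]]
  facs_sample_size: 10000
  observation_days: [0, 1, 2, 3, 4, 5, 6, 7, 8]
  n_initial_negative: 1000
  mammosphere:
    n_initial_negative: 1
    t_end: 10.0
    threshold: 20
    n_runs: 100
hypoxia:
  params:
    alpha_S: 0.4
    delta_S: 0.1
    alpha_D: 0.45
    delta_D: 0.1
    k_SD: 0.1
    k_DS: [[0.0, 0.002], [3.0, 0.02]]
  facs_sample_size: 10000
  observation_days: [0, 1, 2, 3, 4, 5, 6, 7, 8]
  n_initial_negative: 1000
  mammosphere:
    n_initial_negative: 1
    t_end: 10.0
    threshold: 20
    n_runs: 100
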