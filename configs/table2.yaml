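# Operating characteristics of the four locally optimal designs, n = 40.
alpha_tox: -6.0
beta_tox: 0.72
alpha_eff: -3.5
beta_eff: 1.0
gamma: 0.2
dose_lower: 0.0
dose_upper: 10.0
n: 40
n_reps: 1000
seed: 1
designs:
  - label: I
    doses: [2.22, 5.31, 9.95]
    weights: [0.304, 0.449, 0.247]
  - label: II
    doses: [2.33, 4.42, 6.41]
    weights: [0.409, 0.182, 0.409]
  - label: III
    doses: [4.55, 8.33]
    weights: [0.635, 0.365]
  - label: IV
    doses: [3.61, 6.41]
    weights: [0.376, 0.624]
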