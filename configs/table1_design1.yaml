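# Unrestricted D-optimal design for the worked-example CR model.
alpha_tox: -6.0
beta_tox: 0.72
alpha_eff: -3.5
beta_eff: 1.0
gamma: 0.2
dose_lower: 0.0
dose_upper: 10.0
criterion: D
restricted: false
seed: 1
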