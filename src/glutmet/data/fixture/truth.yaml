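alpha:
- 0.8
- 0.0
alpha0: 0.0
baseline_high: 10.0
baseline_low: 4.0
beta:
- 0.5
- 0.5
beta0: 0.0
delta:
- 0.5
- 0.0
loading_high: 1.2
loading_low: 0.8
n_background: 30
n_cancer: 12
n_control: 12
seed: 7
sigma: 1.0
tau: 0.3
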