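# Full-scale reference configuration: deterministic CH, constant mobility,
# unit sphere. 64 realizations of this run (surfchc ensemble --config ...
# --n 64) reproduce the constant-mobility growth-rate statistics.
# Multi-day on a single CPU; intended for cluster or overnight use.
shape: sphere
grid: {N: 129}
params:
  Cn: 0.015
  Pe: 1.0
  sigma: 0.0
  mobility: constant
  mean_concentration: 0.3
  perturbation_amplitude: 0.01
  # dt defaults to 5.12e-3 * h
run: {t_end: 10.0, record_stride: 50}
analysis: {fit_window: [0.1, 10.0]}
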