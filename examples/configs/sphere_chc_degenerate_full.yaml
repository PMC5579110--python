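# Full-scale CHC with degenerate mobility 4 f (1 - f) and noise
# sigma = 1e-5; the fastest-coarsening case. The fit window ends at
# t = 0.8 because this case reaches the slow late-time regime sooner.
shape: sphere
grid: {N: 129}
params:
  Cn: 0.015
  sigma: 1.0e-5
  mobility: degenerate
run: {t_end: 10.0, record_stride: 50}
analysis: {fit_window: [0.1, 0.8]}
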