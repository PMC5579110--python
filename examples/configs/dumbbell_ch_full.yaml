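# Full-scale dumbbell run, constant mobility. The dumbbell spans
# [-1.875, 1.875] along x, so the domain is enlarged accordingly.
# Two growth regimes exist: fit [0.02, 0.2] (early) and [1, 10] (late).
shape: dumbbell
grid:
  N: 193
  lower: [-2.0, -2.0, -2.0]
  upper: [2.0, 2.0, 2.0]
params:
  Cn: 0.015
  sigma: 0.0
  mobility: constant
run: {t_end: 10.0, record_stride: 50}
analysis: {fit_window: [1.0, 10.0]}
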