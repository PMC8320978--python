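# Run configuration for the synthetic refinery-style fixture.
model:
  mean:
    form: rational            # a1 + a2*steam/(steam + a3) + a4*temp (+ beta*x)
    link: cloglog
    covariates: [steam, temp]
    uses_error_prone: true
  precision:
    form: linear              # constant log-precision
    link: log
    covariates: []
    uses_error_prone: false
columns:
  response: y
  error_prone: w
measurement_error:
  calibration: examples/fcc_like_calibration.csv
estimation:
  methods: [naive, rc, aml, pml]
  Q: 50
  levels: [0.90, 0.95, 0.99]
  seed: 1
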