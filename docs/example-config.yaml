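# Example run configuration. One namespace per module; flags passed on
# the command line override these values, which override the built-in
# defaults (the reference parameter tables).

ode:
  t_end: 200
  params:          # coefficient overrides applied on top of the preset
    alpha_na_c: 0.5

spatial:
  scenario: immune-excluded
  n: 128           # grid cells per side
  length: 150.0    # window size, um
  t_end: 35.0
  params:          # overrides on top of the reference table
    tau_t: 25.0
    tau_na: 25.0
    lambda_ct: 75000.0   # the documented low-attraction alternative
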