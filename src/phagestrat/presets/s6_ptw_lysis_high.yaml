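name: s6_ptw_lysis_high
strategy: PTW
command: bifurcation
params:
  s_max: 0.66
analysis:
  N0_grid:
    start: 0.6
    stop: 30.0
    num: 60
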