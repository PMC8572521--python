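name: s7_ptw_shunt_off
strategy: PTW
command: bifurcation
params:
  shunt_enabled: false
analysis:
  N0_grid:
    start: 0.6
    stop: 30.0
    num: 60
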