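name: fig5_ptw_period
strategy: PTW
command: sweep
analysis:
  sweep_axis: period
  N0_grid:
    start: 0.6
    stop: 8.0
    num: 25
  period_grid:
    start: 24.0
    stop: 8760.0
    num: 25
    log: true
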