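name: fig6_ptw_low_growth
strategy: PTW
command: sweep
params:
  y1: 3.75
  y2: 2.0
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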