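name: fig5_lytic_amplitude
strategy: LYTIC
command: sweep
analysis:
  sweep_axis: amplitude
  N0_grid:
    start: 0.6
    stop: 8.0
    num: 25
  amplitude_grid:
    start: 0.0
    stop: 0.99
    num: 25
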