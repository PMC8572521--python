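name: fig4_lytic_const
strategy: LYTIC
command: bifurcation
analysis:
  N0_grid:
    start: 0.6
    stop: 30.0
    num: 60
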