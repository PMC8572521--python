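name: fig4_ptl_fluct
strategy: PTL
command: bifurcation
analysis:
  N0_grid:
    start: 0.6
    stop: 30.0
    num: 60
  fluctuating: true
  fluct_amplitude: 0.5
  fluct_period: 168.0
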