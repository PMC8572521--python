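name: fig3_ptl
strategy: PTL
command: timeseries
params:
  N0: 2.0
simulation:
  t_end: 4800.0
  transient_fraction: 0.0
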