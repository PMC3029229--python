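# 1 Hz steady pacing of the base (vCa) variant, six beats from the cached
# paced steady state.  Run with:  atriasim simulate examples/steady_1hz.yaml
protocol:
  kind: steady_pacing
  frequency_hz: 1.0
  n_beats: 6
variant: vCa
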