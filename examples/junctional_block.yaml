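# Block the junctional SR release site at t = 1 s during 1 Hz pacing.
protocol:
  kind: release_block
  block_target: junctional
  t_on_ms: 1000.0
  n_beats: 6
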