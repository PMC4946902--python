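# A study shaped like the smaller study preset: 11 analysis blocks (five
# recording days split into 100+-trial blocks), ten cue lines per trial,
# lower neuron counts.  Pair with criterion_deg: 90 in the tuning step.
n_sessions: 11
n_lines: 10
n_center_out: 80
n_per_condition: 100
neurons:
  n_pmd: 24
  n_m1: 12
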