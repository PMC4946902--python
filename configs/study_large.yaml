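# A study shaped like the larger study preset: 27 sessions, five cue lines per
# trial, ~40 premotor and ~20 motor-cortex neurons per session.
n_sessions: 27
n_lines: 5
n_center_out: 80
n_per_condition: 150
neurons:
  n_pmd: 40
  n_m1: 20
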