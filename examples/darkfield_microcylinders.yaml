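# Dark-field study of the PMMA microcylinder phantom (desk scale).
experiment: darkfield
params:
  n_angles: 40
  n_histories: 30000
  seed: 0
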