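# Propagation-based edge profiles of the hollow polypropylene cylinder.
experiment: propagation
params:
  energy: 10.0
  n_histories: 400000
  seed: 3
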