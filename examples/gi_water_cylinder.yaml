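# Grating-interferometry tomography of a water cylinder in air (desk scale).
experiment: gi_tomography
params:
  energy: 25.0          # keV
  n_angles: 60
  n_histories: 100000
  n_steps: 5
  cutoff: 10.0          # keV
  seed: 42
phantom:
  builtin: cylinder
  params:
    radius: 0.75e-3     # m
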