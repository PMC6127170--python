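# Majority design run: all 3-species / 3-reaction bimolecular networks.
problem: majority
grid: [[3, 3]]
stutter_bound: 10
seed: 1
optimizer:
  burn_in: 200
  samples: 200
  log10_rate_bounds: [-3, 2]
  proposal_sd: 0.5
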