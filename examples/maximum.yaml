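# Maximum design run: 4 species / 3 reactions (none exist with 3 species).
problem: maximum
grid: [[4, 3]]
stutter_bound: 10
seed: 1
optimizer:
  burn_in: 200
  samples: 200
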