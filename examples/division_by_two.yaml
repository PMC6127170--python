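# Division-by-two design run: single-reaction networks over 3 species.
problem: division_by_two
grid: [[3, 1]]
stutter_bound: 10
seed: 1
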