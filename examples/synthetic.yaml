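# Parameters for the synthetic phantom studies. The only deviation from the
# built-in defaults is the contraction neighbourhood, matched to the
# synthetic surface density (~0.5 points/mm^2); see docs/methods.md.
contraction:
  k_neighbors: 16
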