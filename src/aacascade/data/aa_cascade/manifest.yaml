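name: aa_cascade
compartments:
- id: intracellular
  volume_l: 1.0e-12
- id: extracellular
  volume_l: 1.0e-09
species_file: species.tsv
reactions_file: reactions.tsv
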