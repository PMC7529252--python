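name: xy_univalent_random_chromatids
mII_rule: random_chromatids
chromosomes:
- name: XY
  conjunction: univalent_pair
  homologs:
  - label: X
    dna_content: 1.0
    probe: red
  - label: Y
    dna_content: 1.0
    probe: green
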