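name: conjunction_null_regular_sisters
mII_rule: regular_sisters
chromosomes:
- name: XY
  conjunction: univalent_pair
  homologs:
  - label: X
    dna_content: 42.0
    probe: red
  - label: Y
    dna_content: 40.0
    probe: green
- name: '2'
  conjunction: univalent_pair
  homologs:
  - label: 2a
    dna_content: 48.0
    probe: none
  - label: 2b
    dna_content: 48.0
    probe: none
- name: '3'
  conjunction: univalent_pair
  homologs:
  - label: 3a
    dna_content: 52.0
    probe: none
  - label: 3b
    dna_content: 52.0
    probe: none
- name: '4'
  conjunction: univalent_pair
  homologs:
  - label: 4a
    dna_content: 4.3
    probe: none
  - label: 4b
    dna_content: 4.3
    probe: none
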