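# Default semantic-type filter: functional types allowed for linking (B)
# concepts and substance-like types allowed for target (C) concepts.
linking_types:
  - Biologic function
  - Cell function
  - Finding
  - Molecular function
  - Organism function
  - Organ or tissue function
  - Pathologic function
  - Phenomenon or process
  - Physiologic function
target_types:
  - Organic chemical
  - Lipid
  - Pharmacologic substance
  - Vitamin
  - Element, ion, or isotope
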