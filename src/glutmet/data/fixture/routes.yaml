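synthetic_product:
  product:
  - PROD
  reactants:
    r1:
    - R1
    r2:
    - R2
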