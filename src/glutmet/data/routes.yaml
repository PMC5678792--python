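# Substrate -> product reaction routes.
#
# Each product pathway names the process gene groups whose combined
# expression defines the product's activity, plus one route per reactant
# metabolite (synthesis and/or uptake process groups combined into a
# single predictor, except where sources are deliberately split, as for
# glutathione's glutamate-from-synthesis vs glutamate-from-transport).
purine:
  product: [B1, B2, B3, B4]
  reactants:
    glutamine: [A1, A2]
    adenosine: [B5]
    guanosine: [B6]
    inosine: [B7]
pyrimidine:
  product: [C1, C2, C3]
  reactants:
    glutamine: [A1, A2]
    cytidine: [C4]
    uridine: [C5]
atp:
  product: [D1, D2]
  reactants:
    glutamine: [A1, A2]
    glucose: [D3]
lipid:
  product: [E1]
  reactants:
    glutamine: [A1, A2]
    glucose: [D3]
nucleotide:
  product: [B1, B2, B3, B4, C1, C2, C3]
  reactants:
    glutamine: [A1, A2]
    glucose: [D3]
udp_glcnac:
  product: [F1, F2]
  reactants:
    glutamine: [A1, A2]
    glucosamine: [F3]
asparagine:
  product: [G1]
  reactants:
    glutamine: [A1, A2]
proline:
  product: [H1, H2]
  reactants:
    glutamine: [A1, A2]
    arginine: [H4, H5]
serine:
  product: [I1]
  reactants:
    glutamate: [A3, A4]
gsh:
  product: [J1]
  reactants:
    glu_synt: [A4]
    glu_trsp: [A3]
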