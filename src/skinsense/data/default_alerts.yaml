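# Default skin-protein reactive-group alert library.
# Curated domain-standard SMARTS for the canonical electrophilic reaction
# domains of the skin-sensitization adverse outcome pathway. A custom
# library in the same format is a drop-in replacement.
alerts:
  - id: michael_acceptor_enone
    smarts: "[CX3]=[CX3]-[CX3]=[OX1]"
    mechanism: Michael addition
    source: alpha,beta-unsaturated carbonyl
  - id: michael_acceptor_enal
    smarts: "[CX3]=[CX3]-[CX3H1]=[OX1]"
    mechanism: Michael addition
    source: alpha,beta-unsaturated aldehyde
  - id: michael_acceptor_nitrovinyl
    smarts: "[CX3]=[CX3]-[N+](=O)[O-]"
    mechanism: Michael addition
    source: nitroalkene
  - id: quinone
    smarts: "O=C1C=CC(=O)C=C1"
    mechanism: Michael addition
    source: para-quinone
  - id: aldehyde_schiff
    smarts: "[CX3H1](=O)[#6]"
    mechanism: Schiff base formation
    source: aliphatic/aromatic aldehyde
  - id: alpha_diketone
    smarts: "[CX3](=[OX1])[CX3](=[OX1])"
    mechanism: Schiff base formation
    source: 1,2-dicarbonyl
  - id: acyl_halide
    smarts: "[CX3](=[OX1])[F,Cl,Br,I]"
    mechanism: Acyl transfer
    source: acid halide
  - id: anhydride
    smarts: "[CX3](=[OX1])[OX2][CX3](=[OX1])"
    mechanism: Acyl transfer
    source: carboxylic anhydride
  - id: isocyanate
    smarts: "[NX2]=[CX2]=[OX1]"
    mechanism: Acyl transfer
    source: isocyanate/carbamoylation
  - id: isothiocyanate
    smarts: "[NX2]=[CX2]=[SX1]"
    mechanism: Acyl transfer
    source: isothiocyanate
  - id: alkyl_halide_sn2
    smarts: "[CX4;!$(C(F)(F)F);CH2,CH1,CH3][Cl,Br,I]"
    mechanism: SN2
    source: primary/secondary alkyl halide
  - id: sulfonate_ester
    smarts: "[CX4][OX2][SX4](=[OX1])(=[OX1])"
    mechanism: SN2
    source: alkyl sulfonate ester
  - id: epoxide
    smarts: "[#6;r3]1[#6;r3][OX2;r3]1"
    mechanism: SN2
    source: epoxide ring opening
  - id: aziridine
    smarts: "[#6;r3]1[#6;r3][NX3;r3]1"
    mechanism: SN2
    source: aziridine ring opening
  - id: beta_lactone
    smarts: "O=C1OCC1"
    mechanism: SN2
    source: beta-lactone
  - id: snar_nitro_haloaromatic
    smarts: "[F,Cl,Br,I]c1ccc([N+](=O)[O-])cc1"
    mechanism: SNAr
    source: para-nitro activated haloaromatic
  - id: snar_nitro_haloaromatic_ortho
    smarts: "[F,Cl,Br,I]c1c([N+](=O)[O-])cccc1"
    mechanism: SNAr
    source: ortho-nitro activated haloaromatic
  - id: snar_haloazine
    smarts: "[F,Cl,Br,I]c1ncccn1"
    mechanism: SNAr
    source: 2-halopyrimidine
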