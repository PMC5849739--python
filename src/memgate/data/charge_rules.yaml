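# Charge-class rules: which atoms carry formal positive/negative charge for
# electrostatic contact counting. Protein side-chain defaults plus headgroup
# atoms of common dioleoyl phospholipids (CHARMM atom names).
protein:
  ARG: {NE: pos, NH1: pos, NH2: pos}
  LYS: {NZ: pos}
  ASP: {OD1: neg, OD2: neg}
  GLU: {OE1: neg, OE2: neg}
  # His ring nitrogens are positive only when the residue is listed as
  # protonated-cationic (doubly protonated); neutral by default.
  HIS_CATIONIC: {ND1: pos, NE2: pos}
lipids:
  DOPC:
    O11: neg
    O12: neg
    O13: neg
    O14: neg
    N: pos
  DOPE:
    O11: neg
    O12: neg
    O13: neg
    O14: neg
    N: pos
  # PG carries a net anionic phosphate; its glycerol headgroup is neutral.
  DOPG:
    O11: neg
    O12: neg
    O13: neg
    O14: neg
acidic_oxygens:
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]
phosphate_atoms: [P, O11, O12, O13, O14]
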