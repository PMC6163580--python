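# Residue hydropathy classes and bead radii (nm) for CG / CA-reduced systems.
# Classes: hydrophobic, polar, charged_pos, charged_neg, other.
# The default radius follows the regular MARTINI particle (0.26 nm).
default_radius_nm: 0.26
residues:
  ALA: {class: hydrophobic}
  VAL: {class: hydrophobic}
  LEU: {class: hydrophobic}
  ILE: {class: hydrophobic}
  MET: {class: hydrophobic}
  PHE: {class: hydrophobic}
  TRP: {class: hydrophobic}
  PRO: {class: hydrophobic}
  CYS: {class: hydrophobic}
  GLY: {class: polar}
  SER: {class: polar}
  THR: {class: polar}
  TYR: {class: polar}
  ASN: {class: polar}
  GLN: {class: polar}
  HIS: {class: polar}
  LYS: {class: charged_pos}
  ARG: {class: charged_pos}
  ASP: {class: charged_neg}
  GLU: {class: charged_neg}
  # non-natural residues of peptergent sequences
  ADA: {class: hydrophobic}   # 2-aminodecanoic acid, isoleucine-like
  ABZ: {class: hydrophobic}   # aminobenzoyl cap, phenylalanine-like
  # dodecylphosphocholine detergent beads (head / tail residue names)
  DPC: {class: other}
  PCH: {class: polar}         # phosphocholine head
  DTL: {class: hydrophobic}   # dodecyl tail
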