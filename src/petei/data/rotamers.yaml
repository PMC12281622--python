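# Minimal backbone-independent side-chain rotamer set: the highest-population
# chi combinations per residue type (gauche-/trans/gauche+ staples).  Intended
# as a self-contained default; a full Dunbrack-style text table can be loaded
# at run time instead (see interaction_geometry.load_rotamer_table).
version: 1
rotamers:
  SER:
    - {chis: [-65.0], prob: 0.48}
    - {chis: [178.0], prob: 0.29}
    - {chis: [64.0], prob: 0.23}
  CYS:
    - {chis: [-65.0], prob: 0.55}
    - {chis: [178.0], prob: 0.26}
    - {chis: [64.0], prob: 0.19}
  THR:
    - {chis: [-60.0], prob: 0.49}
    - {chis: [59.0], prob: 0.43}
    - {chis: [180.0], prob: 0.08}
  VAL:
    - {chis: [175.0], prob: 0.73}
    - {chis: [-64.0], prob: 0.20}
    - {chis: [63.0], prob: 0.07}
  LEU:
    - {chis: [-65.0, 175.0], prob: 0.59}
    - {chis: [-177.0, 63.0], prob: 0.29}
    - {chis: [-85.0, 65.0], prob: 0.12}
  ILE:
    - {chis: [-65.0, 169.0], prob: 0.60}
    - {chis: [-57.0, -60.0], prob: 0.15}
    - {chis: [62.0, 170.0], prob: 0.25}
  MET:
    - {chis: [-65.0, 180.0, -70.0], prob: 0.40}
    - {chis: [-65.0, -65.0, -70.0], prob: 0.30}
    - {chis: [180.0, 180.0, 75.0], prob: 0.30}
  ASP:
    - {chis: [-70.0, -15.0], prob: 0.51}
    - {chis: [-177.0, 2.0], prob: 0.31}
    - {chis: [63.0, 2.0], prob: 0.18}
  ASN:
    - {chis: [-65.0, -40.0], prob: 0.47}
    - {chis: [-174.0, -42.0], prob: 0.30}
    - {chis: [63.0, 53.0], prob: 0.23}
  GLU:
    - {chis: [-67.0, 180.0, -10.0], prob: 0.44}
    - {chis: [-177.0, 175.0, -5.0], prob: 0.33}
    - {chis: [-65.0, -68.0, -40.0], prob: 0.23}
  GLN:
    - {chis: [-67.0, 180.0, -25.0], prob: 0.44}
    - {chis: [-177.0, 175.0, -100.0], prob: 0.31}
    - {chis: [-65.0, -65.0, -40.0], prob: 0.25}
  LYS:
    - {chis: [-67.0, 180.0, 180.0, 180.0], prob: 0.40}
    - {chis: [-177.0, 180.0, 180.0, 180.0], prob: 0.35}
    - {chis: [-67.0, -68.0, 180.0, 180.0], prob: 0.25}
  ARG:
    - {chis: [-67.0, 180.0, 180.0, 180.0], prob: 0.38}
    - {chis: [-177.0, 180.0, 180.0, 180.0], prob: 0.34}
    - {chis: [-67.0, -68.0, 180.0, 180.0], prob: 0.28}
  HIS:
    - {chis: [-65.0, -70.0], prob: 0.45}
    - {chis: [-177.0, 65.0], prob: 0.33}
    - {chis: [63.0, -75.0], prob: 0.22}
  PHE:
    - {chis: [-65.0, 90.0], prob: 0.51}
    - {chis: [-177.0, 80.0], prob: 0.34}
    - {chis: [63.0, 90.0], prob: 0.15}
  TYR:
    - {chis: [-65.0, 90.0], prob: 0.52}
    - {chis: [-177.0, 80.0], prob: 0.34}
    - {chis: [63.0, 90.0], prob: 0.14}
  TRP:
    - {chis: [-65.0, 95.0], prob: 0.39}
    - {chis: [-177.0, -105.0], prob: 0.34}
    - {chis: [63.0, -90.0], prob: 0.27}
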