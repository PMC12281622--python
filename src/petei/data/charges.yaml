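# Simple residue-template partial charges (elementary charge units) and
# formal-charge classes at physiological pH.  Only ionizable side-chain
# groups carry nonzero partial charge in this template; histidine is
# treated as neutral throughout.
version: 1
partial_charges:
  LYS: {NZ: 1.0}
  ARG: {NE: 0.2, NH1: 0.4, NH2: 0.4}
  ASP: {OD1: -0.5, OD2: -0.5}
  GLU: {OE1: -0.5, OE2: -0.5}
formal_charge_class:
  positive:
    LYS: [NZ]
    ARG: [NE, NH1, NH2]
  negative:
    ASP: [OD1, OD2]
    GLU: [OE1, OE2]
# Lennard-Jones well depths (kcal/mol) and rmin/2-style radii (Å) per element,
# combined with Lorentz-Berthelot rules.
lennard_jones:
  H: {epsilon: 0.046, rmin_half: 0.22}
  C: {epsilon: 0.11, rmin_half: 2.00}
  N: {epsilon: 0.20, rmin_half: 1.85}
  O: {epsilon: 0.12, rmin_half: 1.70}
  S: {epsilon: 0.45, rmin_half: 2.00}
  P: {epsilon: 0.58, rmin_half: 2.15}
  default: {epsilon: 0.11, rmin_half: 2.00}
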