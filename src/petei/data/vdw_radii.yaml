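# Element-based van der Waals radii (Å), Bondi-style values.
# Used for both clash definitions (full-sum "database" rule and the
# 80%-of-sum "design" rule).  User-overridable via config.
version: 1
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  SE: 1.90
  F: 1.47
  CL: 1.75
  BR: 1.85
  I: 1.98
default: 1.70
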