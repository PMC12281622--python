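# Ideal interaction geometries searched for around binding loops and epitopes.
# Each family pairs a "projection" site (a point in space, at the ideal
# distance from an emitting group, where the partner's key atom or ring
# center should sit) with an "anchor" site (the partner key atom / ring
# center itself).  Distances in Å.
version: 1
families:
  hbond_NH_OC:
    description: hydrogen bond, N-H donor to carbonyl O acceptor
    distance: 2.89
    projection_from: NH_donor
    anchor: carbonyl_O
    secondary: head_on
  hbond_NH_OH:
    description: hydrogen bond, N-H donor to hydroxyl O acceptor
    distance: 3.00
    projection_from: NH_donor
    anchor: hydroxyl_O
    secondary: head_on
  hbond_OH_OC:
    description: hydrogen bond, O-H donor to carbonyl O acceptor
    distance: 2.79
    projection_from: OH_donor
    anchor: carbonyl_O
    secondary: head_on
  hbond_OH_OH:
    description: hydrogen bond, O-H donor to hydroxyl O acceptor
    distance: 2.86
    projection_from: OH_donor
    anchor: hydroxyl_O
    secondary: head_on
  salt_bridge_arg:
    description: Arg guanidinium C to Asp/Glu carboxylate C salt bridge
    distance: 3.96
    projection_from: arg_cation
    anchor: carboxylate_C
    secondary: head_on
  salt_bridge_lys:
    description: Lys ammonium N to Asp/Glu carboxylate C salt bridge
    distance: 3.18
    projection_from: lys_cation
    anchor: carboxylate_C
    secondary: head_on
  cation_pi_arg:
    description: Arg guanidinium C over an aromatic ring center
    distance: 3.75
    projection_from: aromatic_ring
    anchor: arg_cation
    secondary: head_on
  cation_pi_lys:
    description: Lys ammonium N over an aromatic ring center
    distance: 4.20
    projection_from: aromatic_ring
    anchor: lys_cation
    secondary: head_on
  pipi_parallel:
    description: parallel-displaced aromatic ring stacking
    distance: 3.75          # vertical displacement along the ring normal
    horizontal_offset: 1.50 # in-plane displacement of the partner ring center
    projection_from: aromatic_ring
    anchor: aromatic_ring
    secondary: parallel_planes
  pipi_tshaped:
    description: T-shaped aromatic ring stacking
    distance: 5.00
    projection_from: aromatic_ring
    anchor: aromatic_ring
    secondary: perpendicular_planes
  hispi_parallel:
    description: parallel histidine ring over an aromatic ring
    distance: 3.50
    projection_from: his_ring
    anchor: aromatic_ring
    secondary: parallel_planes
  hispi_tshaped:
    description: T-shaped histidine ring against an aromatic ring
    distance: 4.25
    projection_from: his_ring
    anchor: aromatic_ring
    secondary: perpendicular_planes
secondary_cone_deg: 20.0
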