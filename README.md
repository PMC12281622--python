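# petei

Computational design of monobody-style binding proteins for short peptide
epitopes (e.g. HA-, FLAG-, or MYC-tag-like targets), built on a fibronectin
type III (FN3) scaffold whose three binding loops are replaced by loops
harvested from a structure corpus.

The package is for structural bioinformaticians and protein engineers who
want a self-contained, deterministic implementation of hotspot-driven binder
design: instead of exhaustively docking and scoring, it searches for rigid
placements of the target in which several *exceptional* interactions —
hydrogen bonds, salt bridges, cation–π and π–π contacts near their
thermodynamically ideal geometry — form simultaneously between the target
epitope and the binding loops.

## Method

**Stage 1 — loop database.** A loop slot on the scaffold is described by its
two attachment-point residues *i* and *f*. A candidate segment from the
corpus matches a slot when all seven flank distances

> Cα·i–Cα·f, Cβ·i–Cβ·f, Cα·i–Cβ·f, Cβ·i–Cα·f, N·i–N·f, O·i–O·f, C·i–C·f

agree with the scaffold's to within 0.225 Å (glycine uses an ideally
constructed virtual Cβ). Matched loops are superposed onto the scaffold by a
least-squares fit of the eight flank backbone atoms and screened for
compatibility: at most 16 heavy-atom steric clashes (two heavy atoms closer
than the sum of their van der Waals radii) and an interaction energy of at
most 237.5 kcal/mol against the loop-less scaffold; at most 3 clashes and
55.6 kcal/mol against loops of other slots. These cutoffs correspond to the
worst decile of antibody CDRs, the structural analogue of monobody loops.
Loops lacking a compatible partner in any other slot are pruned iteratively.
For every retained loop, the spatial positions where ideal interactions
could form around it are precomputed over native side-chain conformations
plus a library of rotamers (no mutations are ever introduced).

**Stage 2 — binder design.** The target is oriented so the declared epitope
is centered on the z-axis facing the loops; the one unconstrained rotational
degree of freedom is swept in 1° increments about z while translations are
solved directly: each complementary (epitope site, loop site) pair proposes
a translation, and a proposal is accepted when at least a minimum number
(default 4) of complementary interactions match one-to-one within 0.33 Å.
Accepted placements are screened for three detrimental features —
≥2 steric clashes at the 80%-of-vdW-sum rule among backbone atoms and
interacting side chains, any like-charge pair within 4.2 Å (Lys/Arg
nitrogens positive, Asp/Glu carboxylate oxygens negative; His is neutral),
and more than 3 positively charged loop residues. Partial designs are
completed from the database, near-duplicates (>60% shared loop IDs) are
discarded, clashing non-interacting side chains are greedily repacked, and
survivors are ranked by **binding energy per buried surface area (BE/BSA)**,
most negative first. Energies are a simplified Coulomb + Lennard-Jones model
(not CHARMM/Rosetta-compatible); surface areas are Shrake–Rupley.

## Worked example

All inputs can be generated offline. Build a loop database from a synthetic
corpus with planted matches:

```bash
petei fixtures --preset corpus --seed 7 --out fx
petei build-db --scaffold fx/scaffold.pdb \
    --slot 1:A:4-7 --slot 2:A:15-19 --slot 3:A:27-32 \
    --corpus fx/corpus --out db
```

which prints

```
database: 14 loops in 3 slots, 65 compatible pairs, combinatorial diversity 100
```

— 14 of the 15 planted loops survived compatibility screening (one arcs into
the scaffold body), none of the 60 perturbed decoys matched, and the slots
multiply out to 100 loop combinations. Then design binders against a toy
epitope whose loop database is engineered to present four complementary
interaction sites:

```bash
petei fixtures --preset rigged --seed 7 --out rig
petei design --db rig/db --scaffold rig/scaffold.pdb \
    --slot 1:A:4-7 --slot 2:A:15-19 --slot 3:A:27-32 \
    --target rig/target.pdb --epitope T:1-10 \
    --rotation-step 5 --out designs
```

`designs/designs.tsv` then contains one ranked design:

```
design_id             loops                              rotation_deg  tx      ty      tz     n_matches  BE        BSA     BE_BSA
d00000_r0+rig3/A/2-7  rig1/A/2-9;rig2/A/2-13;rig3/A/2-7  0             -0.0088 -0.0310 7.9832 4          -34.8265  314.21  -0.110837
```

The design matched all 4 planted interactions (one Lys–Asp salt bridge and
three hydroxyl hydrogen bonds) at rotation 0°, passed all three screens,
completed its third loop from the database, and buries 314 Å² of surface at
−34.8 kcal/mol, i.e. BE/BSA = −0.111 kcal/(mol·Å²). A per-design PDB file of
the complex is written alongside the table.

The same pipeline runs on real structures: point `--scaffold` at an FN3
domain, `--slot` at the loop ranges to replace, `--corpus` at a directory of
PDB files, and `--target`/`--epitope` at the peptide to bind.

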