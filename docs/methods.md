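# Methods

This note documents the models, conventions, and numerical choices behind the
package, in the spirit of a software methods section. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and assumptions

The pipeline designs rigid-backbone binders: harvested loops keep their
experimentally observed (or, in fixtures, constructed) backbone and native
sequence — no mutations, no backbone minimization. Binding is assumed to
occur at physiological pH, so histidine is never treated as charged.
Hydrogens are dropped at parse time; every geometric rule operates on heavy
atoms, with donor-hydrogen directions inferred from heavy-atom geometry
(amide H along the bisector of the N's two bonds; side-chain N–H/O–H along
the terminal bond extension). Multi-model (NMR) inputs use the first model
only. Alternate locations resolve to the highest-occupancy copy, ties to the
first encountered.

## Geometry conventions

* **Attachment signature.** Seven inter-flank distances (CAi–CAf, CBi–CBf,
  CAi–CBf, CBi–CAf, Ni–Nf, Oi–Of, Ci–Cf), compared per distance with an
  *inclusive* tolerance (default 0.225 Å; "within" is read as ≤, with a 1e-9
  guard so a constructed deviation of exactly 0.225 matches and 0.226 does
  not). Glycine flanks use a virtual Cβ placed 1.53 Å from Cα along the
  ideal tetrahedral direction; the construction commutes with rigid motions.
* **Superposition.** Least-squares (Kabsch) fit of the eight flank backbone
  atoms (N, CA, C, O of i and f). Candidate signatures are computed on the
  candidate's own geometry — distances are frame-invariant, so the order of
  matching and superposition is immaterial.
* **Loop candidates.** Contiguous runs are split at peptide bonds longer
  than 2.0 Å; candidate interior lengths default to 4–20 residues; duplicate
  (source, range, slot) segments are removed; output order is sorted by loop
  id so database builds are reproducible.
* **Scaffold/target frames.** The scaffold sits with the attachment-point
  centroid at the origin and loops toward +z. The target is canonically
  oriented: the vector from the non-epitope body centroid to the epitope
  centroid is aligned with −z, the epitope centroid is placed at
  (0, 0, `epitope_height`) (default 5 Å; the translational solve absorbs any
  offset, so this is presentation, not physics), and the residual azimuth is
  fixed by pointing the first epitope residue's Cα toward +x in the xy
  plane. If the epitope spans the whole structure, the orientation falls
  back to the epitope's principal axis with a warning.

## Interaction model

Twelve interaction families cover thirteen ideal-geometry rows (the
parallel-displaced π–π row contributes both a vertical 3.75 Å and a lateral
1.50 Å displacement): N–H→O=C 2.89, N–H→O–H 3.00, O–H→O=C 2.79,
O–H→O–H 2.86, Arg(Cζ)–carboxylate(C) 3.96, Lys(Nζ)–carboxylate(C) 3.18,
Arg–π 3.75, Lys–π 4.20, π–π parallel-displaced 3.75/1.50, π–π T-shaped
5.00, His–π parallel 3.50, His–π T-shaped 4.25 (all Å; packaged in
`data/interactions.yaml`).

Sites come in two kinds. A *projection* is the point where the partner's key
atom (or ring center) should sit, emitted at the ideal distance along the
donor/cation/ring axis; an *anchor* is the partner atom or ring center
itself. Rings emit projections along both normals; the parallel-displaced
family emits four lateral offsets around each normal. A complementary match
requires same family, one projection plus one anchor, the family's secondary
angular constraint, and positional coincidence within the match tolerance.

Secondary constraints are operationalized as 20° cones (configurable):
head-on anti-alignment of the emitting axis and the anchor's outward axis
for hydrogen bonds, salt bridges, and cation–π; ring-plane parallelism
(min(θ, 180°−θ) ≤ cone) for stacked geometries; |θ − 90°| ≤ cone for
T-shaped ones. This is a deliberate simplification — real lone-pair
directionality is broader than a head-on cone — and makes the geometric
gates conservative rather than permissive.

Side chains are rebuilt at library rotamers with a NeRF chain construction
from idealized internal coordinates (Engh–Huber-like bond lengths/angles).
The packaged rotamer set (`data/rotamers.yaml`) holds the top 3 backbone-
independent χ combinations per residue type; a loader accepts user-supplied
whitespace tables (`RES χ1 [χ2 χ3 χ4] prob` per line) for larger libraries,
which are not redistributed. Site enumeration covers the native conformation
(rotamer index 0) plus each library rotamer, for loop and epitope residues
alike; a matched epitope-side rotamer is a hypothetical side-chain pose, not
a rebuilt target.

## Energies, surfaces, screens

The screening energy is a pairwise Coulomb + Lennard-Jones sum over
cross-group heavy atoms within a 12 Å cutoff: template partial charges on
ionizable groups only (Lys Nζ +1; Arg guanidinium +1 split over its
nitrogens; Asp/Glu −0.5 per carboxylate oxygen), a distance-independent
dielectric of 4 (a common implicit-solvent choice), and element-based LJ
parameters with Lorentz–Berthelot combining. The numeric thresholds
(237.5 and 55.6 kcal/mol) were calibrated elsewhere under a full force
field; they are applied to this simplified model as-is, so their selectivity
here is dominated by the LJ repulsion of physical overlap. Contributions are
sorted before summation so the energy is exactly symmetric in its arguments.

When a loop is screened against the scaffold, the two attachment residues
are excluded from the scaffold side: after grafting they are the loop's
bonded neighbors, and their sub-van-der-Waals contact is a bond, not an
interaction (a full force field would treat these as bonded exclusions).

Both clash rules use strict inequality: database mode counts heavy-atom
pairs closer than the full vdW-radius sum, design mode closer than 80% of
it. A charge clash is a like-charged pair strictly within 4.2 Å. The design
steric screen counts only pairs among backbone atoms and the side chains of
residues forming matched interactions — other side chains are assumed
repackable — and rejects at ≥2; the evaluation stage then greedily repacks
clashing non-interacting loop side chains over the rotamer library (fewest
clashes wins, native wins ties) with fixed backbone.

SASA is Shrake–Rupley over heavy atoms with a 1.4 Å probe and a
deterministic 960-point golden-angle spiral per atom (no RNG); coincident
identical spheres are collapsed to one. Buried surface area is
SASA(binder) + SASA(target) − SASA(complex); BE/BSA is undefined (flagged,
ranked last) when the interface buries under 1 Å².

## Translation solver

For one z-rotation, each complementary site pair proposes the translation
t = loop_position − epitope_position. A translation satisfies a pair when it
lies in the ball of radius τ (0.33 Å) around that pair's proposal, so
feasible regions are intersections of equal-radius balls, and a region of
depth k is witnessed by the minimum enclosing ball (MEB) center of its k
proposals. Candidates are therefore: every proposal, the midpoint of every
proposal pair within 2τ (in the intersection iff it is nonempty), and the
MEB center of every mutually-close proposal triple. Each candidate's match
count is verified by maximum bipartite matching (Hopcroft–Karp; sites are
used at most once per solution), accepted solutions are re-centered at the
MEB of their matched proposals to minimize the worst deviation, and
near-duplicate placements (<0.05 Å apart) are merged keeping the higher
count. Witnessing is exact up to depth-3 candidate generation; a region
whose boundary is determined by exactly four spheres with no shallower
witness point could in principle be missed, which the oracle-comparison
tests bound empirically (the solver is checked to dominate an exhaustive
0.1 Å grid search and every claim is re-verified by an independent
brute-force matcher). Solutions are additionally made self-consistent: one
loop per slot (the loop with the most matched pairs wins, ties by id) and
one rotamer per residue and side.

The rotation sweep computes epitope sites once and rotates them (sites are
rigidly equivariant, which tests assert), so a full 360-step sweep costs one
enumeration plus 360 solves. Dedup by loop-ID similarity runs in discovery
order before scoring; with three slots, the >60% rule means two retained
designs share at most one loop.

## Synthetic fixtures

Generators produce every input offline: scaffolds, corpora, and benchmarks
are idealized backbones walked along smooth polylines (1.33/1.46/1.52 Å
N→CA→C steps, ~4.31 Å of path per residue), not real protein fragments — so
the repository ships no third-party structure data. The default scaffold has
three loop slots with deliberately separated attachment signatures (flank
chords 6.0/7.5/9.0 Å; a generation-time check errors if any two slots match
within twice the tolerance). Corpus entries copy scaffold flank residues
exactly (planted: all seven deviations 0) or translate the f-flank along the
i→f axis by the decoy perturbation (default 0.5 Å, so the CAi–CAf deviation
exceeds the tolerance exactly); the generator refuses perturbations at or
below the tolerance, which would falsify the labels. The rigged benchmark
engineers one Lys salt-bridge donor and three Ser hydroxyl donors into the
slot-1/slot-2 loops so their projected sites coincide with anchor sites on
the canonically oriented toy epitope, leaves slot 3 inert to exercise the
completion step, and verifies its own designability (orientation, matching,
screening) before returning — a failed construction raises.

Because fixtures are idealized, passing tests demonstrate the correctness of
the geometry, screening, matching, and ranking machinery — exact planted
recovery, oracle agreement, boundary behavior, determinism — but not
biological performance: fixture backbones are not Ramachandran-valid, the
corpus is tiny compared to a real structure database, and the simplified
energy model does not reproduce force-field numerics. Published database
sizes and design counts from full-corpus runs are inputs to the worked
diversity example, not quantities this package re-derives.

## Defaults

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| geometric tolerance | 0.225 | Å | per-distance flank match, inclusive |
| loop length range | 4–20 | residues | candidate interior lengths |
| loop–scaffold screen | ≤16, ≤237.5 | clashes, kcal/mol | worst-decile CDR calibration |
| loop–loop screen | ≤3, ≤55.6 | clashes, kcal/mol | worst-decile CDR-pair calibration |
| match tolerance | 0.33 | Å | site-coincidence radius |
| min interactions | 4 | — | complementary matches per placement |
| rotation step | 1 | degrees | z-sweep increment (must divide 360) |
| steric rejection | ≥2 | clashes | design mode, 80% of vdW sum |
| charge clash | <4.2 | Å | like-charged heavy atoms |
| positive budget | ≤3 | residues | Lys+Arg across loops |
| similarity threshold | 0.60 | fraction | loop-ID dedup |
| dielectric | 4 | — | distance-independent |
| energy cutoff | 12 | Å | pair interactions |
| SASA probe / sampling | 1.4 / 960 | Å / points | Shrake–Rupley |
| secondary cones | 20 | degrees | angular gates |
| epitope height | 5 | Å | canonical epitope centroid z |

## Known limitations

Rigid backbones and discrete rotamers only; the energy model is a screening
stand-in, so BE/BSA values rank designs but are not transferable binding
free energies; depth-4 ball-intersection witnesses are not enumerated (see
above); the one-degree sweep does not super-resolve placements between
steps (adjacent-step duplicates are removed by the similarity rule); and
mmCIF input is not supported beyond what gemmi's PDB reader handles.
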