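"""Stage 2: design binders by matching ideal-interaction sites.

The target is canonically oriented (epitope centroid on the +z axis, epitope
facing -z toward the binding loops), the one remaining rotational degree of
freedom is swept in fixed increments about z, and for every orientation the
search solves for rigid translations of the target that bring at least a
minimum number of complementary interaction-site pairs into coincidence
within a tolerance (0.33 Å by default).

Designs are screened for three detrimental features: steric clashes at the
80%-of-vdW-sum rule involving backbone atoms or the side chains of the
interacting residues (fail at >= 2), any like-charge pair within 4.2 Å, and
more than three positively charged residues across the binding loops.
Partial designs are completed from the loop database, near-duplicate designs
(> 60% shared loop IDs) are discarded, clashing non-interacting side chains
are greedily repacked, and survivors are ranked by binding energy per buried
surface area (most negative first).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.spatial import cKDTree

from .energetics import (
    CHARGE_CLASH_DISTANCE,
    DESIGN_CLASH,
    EnergyParams,
    ComplexScore,
    count_charge_clashes,
    count_clashes,
    score_complex,
)
from .geometry import min_enclosing_ball, rotation_about_z, unit
from .interaction_geometry import (
    DEFAULT_SECONDARY_CONE,
    InteractionSite,
    RotamerSet,
    epitope_sites,
    is_complementary,
    load_packaged_rotamers,
    place_sidechain,
)
from .loop_harvest import AttachmentSpec, LoopDatabase, LoopRecord, scaffold_without_loops
from .structure_model import Residue, StructureModel, concatenate

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O"}
_EPS = 1e-9


@dataclass
class DesignConfig:
    min_interactions: int = 4
    match_tolerance: float = 0.33          # Å
    rotation_step: float = 1.0             # degrees about z
    max_positive_loop_residues: int = 3
    similarity_threshold: float = 0.60
    steric_clash_limit: int = 2            # reject at >= this many
    charge_clash_distance: float = CHARGE_CLASH_DISTANCE
    secondary_cone_deg: float = DEFAULT_SECONDARY_CONE
    merge_tolerance: float = 0.05          # Å, duplicate-placement merging
    completion_cap: int = 5                # completions kept per partial design
    epitope_height: float = 5.0            # Å, canonical epitope centroid z
    epitope_rotamers: bool = True

    def __post_init__(self) -> None:
        if self.min_interactions < 1 or self.match_tolerance <= 0:
            raise ValueError("min_interactions and match_tolerance must be positive")
        if self.rotation_step <= 0 or 360.0 % self.rotation_step != 0:
            raise ValueError("rotation_step must be positive and divide 360")


@dataclass
class PlacementSolution:
    rotation: float
    translation: np.ndarray
    matched_pairs: list[tuple[InteractionSite, InteractionSite, float]]

    @property
    def n_matches(self) -> int:
        return len(self.matched_pairs)


@dataclass
class DesignCandidate:
    design_id: str
    loop_ids: dict[int, Optional[str]]
    placement: PlacementSolution
    screening: dict[str, bool] = field(default_factory=dict)
    score: Optional[ComplexScore] = None

    def loop_id_tuple(self) -> tuple[Optional[str], ...]:
        return tuple(self.loop_ids[s] for s in sorted(self.loop_ids))

    def passed_all(self) -> bool:
        return all(self.screening.values())


# ---------------------------------------------------------------------------
# Target orientation
# ---------------------------------------------------------------------------


def select_epitope(target: StructureModel, selection: str) -> list[Residue]:
    """Resolve a "CHAIN:start-end" (or "CHAIN") selection to residues."""
    if ":" in selection:
        chain_id, rng = selection.split(":", 1)
        start, end = (int(x) for x in rng.split("-", 1)) if "-" in rng else (int(rng), int(rng))
    else:
        chain_id, start, end = selection, None, None
    if chain_id not in target.chains:
        raise KeyError(f"chain {chain_id!r} not found in target")
    if start is None:
        return list(target.chains[chain_id])
    residues = target.select_range(chain_id, start, end)
    if not residues:
        raise KeyError(f"no residues in epitope selection {selection!r}")
    return residues


def _heavy_centroid(residues: Iterable[Residue]) -> np.ndarray:
    pts = [a.coord for r in residues for a in r.atoms if a.is_heavy]
    if not pts:
        raise ValueError("no heavy atoms in selection")
    return np.mean(pts, axis=0)


def orient_target(
    target: StructureModel,
    epitope_residues: Sequence[Residue],
    epitope_height: float = 5.0,
) -> StructureModel:
    """Canonically orient the target: epitope centroid on +z, facing -z.

    The vector from the non-epitope body centroid toward the epitope centroid
    is aligned with -z (the epitope faces the binding loops below), the
    epitope centroid is placed at (0, 0, epitope_height), and the residual
    rotation about z is fixed by pointing the first epitope residue's CA
    (projected into the xy plane) along +x.  The construction is a
    canonicalization: any rigid-transformed copy of the same target maps to
    the same output.
    """
    epi_keys = {(r.chain_id, r.seq_id, r.insertion_code) for r in epitope_residues}
    epi = [r for r in target.residues() if (r.chain_id, r.seq_id, r.insertion_code) in epi_keys]
    if not epi:
        raise ValueError("epitope residues not found in target")
    rest = [r for r in target.residues() if (r.chain_id, r.seq_id, r.insertion_code) not in epi_keys]

    epi_c = _heavy_centroid(epi)
    if rest:
        body_c = _heavy_centroid(rest)
        axis = epi_c - body_c
        if np.linalg.norm(axis) < 1e-6:
            axis = None
    else:
        axis = None
    if axis is None:
        logger.warning("epitope spans the whole structure; falling back to principal axis")
        coords = np.array([a.coord for r in epi for a in r.atoms if a.is_heavy])
        centered = coords - coords.mean(axis=0)
        _u, _s, vt = np.linalg.svd(centered)
        axis = vt[2] if vt[2, 2] <= 0 else -vt[2]  # deterministic sign

    from .geometry import rotation_aligning

    R1 = rotation_aligning(unit(axis), np.array([0.0, 0.0, -1.0]))
    out = target.transform(R1, -(R1 @ epi_c))  # epitope centroid at origin

    # canonical azimuth: first epitope residue CA -> +x in the xy plane
    first = min(epi, key=lambda r: (r.chain_id, r.seq_id, r.insertion_code))
    ca = first.atom("CA").coord if first.has_atom("CA") else first.atoms[0].coord
    ca_t = R1 @ ca - R1 @ epi_c
    xy = np.array([ca_t[0], ca_t[1], 0.0])
    if np.linalg.norm(xy) > 1e-3:
        import math

        theta = -math.degrees(math.atan2(xy[1], xy[0]))
        out = out.transform(rotation_about_z(theta), np.zeros(3))
    return out.translate(np.array([0.0, 0.0, epitope_height]))


# ---------------------------------------------------------------------------
# Rotation sweep and translation solve
# ---------------------------------------------------------------------------


def sweep_rotations(
    target: StructureModel,
    epitope_residues: Sequence[Residue],
    config: Optional[DesignConfig] = None,
    rotamers: Optional[RotamerSet] = None,
) -> Iterator[tuple[float, list[InteractionSite]]]:
    """Yield (angle, epitope site list) for each z-rotation increment.

    The target must already be canonically oriented.  Sites for angle theta
    equal the angle-0 sites rotated by theta (rigid equivariance), which is
    how they are produced.
    """
    config = config or DesignConfig()
    rot = rotamers if rotamers is not None else (
        load_packaged_rotamers() if config.epitope_rotamers else None
    )
    base = epitope_sites(target, list(epitope_residues), rotamers=rot)
    n_steps = int(round(360.0 / config.rotation_step))
    zero = np.zeros(3)
    for k in range(n_steps):
        angle = k * config.rotation_step
        if k == 0:
            yield angle, list(base)
        else:
            R = rotation_about_z(angle)
            yield angle, [s.transformed(R, zero) for s in base]


def _max_one_to_one(pair_list: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximum bipartite matching over (left, right) index pairs.

    Deterministic: indices are remapped in sorted order and the scipy
    Hopcroft-Karp result is post-processed into a sorted pair list.
    """
    if not pair_list:
        return []
    lefts = sorted({p[0] for p in pair_list})
    rights = sorted({p[1] for p in pair_list})
    lmap = {v: i for i, v in enumerate(lefts)}
    rmap = {v: i for i, v in enumerate(rights)}
    rows = [lmap[a] for a, b in pair_list]
    cols = [rmap[b] for a, b in pair_list]
    m = csr_matrix(
        (np.ones(len(pair_list), dtype=np.int8), (rows, cols)),
        shape=(len(lefts), len(rights)),
    )
    match = maximum_bipartite_matching(m, perm_type="column")
    out = []
    pair_set = set(pair_list)
    for li, rj in enumerate(match):
        if rj >= 0 and (lefts[li], rights[rj]) in pair_set:
            out.append((lefts[li], rights[rj]))
    return sorted(out)


def solve_translations(
    epi_sites: Sequence[InteractionSite],
    loop_sites: Sequence[InteractionSite],
    config: Optional[DesignConfig] = None,
    rotation: float = 0.0,
) -> list[PlacementSolution]:
    """Find translations of the target matching enough complementary pairs.

    Each complementary (epitope site, loop site) pair proposes the candidate
    translation ``t = loop_pos - epitope_pos``; for balls of equal radius
    (the match tolerance) around these proposals, additional witness points
    are taken at midpoints of nearby proposal pairs and at min-enclosing-ball
    centers of nearby triples, which together hit every region where two or
    three constraint balls overlap.  Each candidate's full match count is then
    verified with a one-to-one maximum matching, and accepted solutions are
    re-centered at the min-enclosing-ball center of their matched proposals
    (minimizing the worst deviation) and merged when closer than the
    duplicate-placement tolerance.
    """
    config = config or DesignConfig()
    tol = config.match_tolerance
    pairs: list[tuple[int, int]] = []
    for i, e in enumerate(epi_sites):
        for j, l in enumerate(loop_sites):
            if is_complementary(e, l, config.secondary_cone_deg):
                pairs.append((i, j))
    if len(pairs) < config.min_interactions:
        return []

    centers = np.array(
        [loop_sites[j].position - epi_sites[i].position for i, j in pairs]
    )
    tree = cKDTree(centers)

    candidates: list[np.ndarray] = [c for c in centers]
    close = tree.query_pairs(2.0 * tol, output_type="ndarray")
    for a, b in close:
        candidates.append((centers[a] + centers[b]) / 2.0)
    # triples: only among mutually close proposals
    neighbor_sets = [set(tree.query_ball_point(c, 2.0 * tol)) for c in centers]
    for a, b in close:
        for c in sorted(neighbor_sets[a] & neighbor_sets[b]):
            if c <= b:
                continue
            center, radius = min_enclosing_ball([centers[a], centers[b], centers[c]])
            if radius <= tol + _EPS:
                candidates.append(center)

    solutions: list[PlacementSolution] = []
    seen_counts: dict[int, int] = {}
    for t in candidates:
        idx = tree.query_ball_point(t, tol + _EPS)
        if len(idx) < config.min_interactions:
            continue
        local = [pairs[k] for k in sorted(idx)]
        matched = _max_one_to_one(local)
        if len(matched) < config.min_interactions:
            continue
        # polish: recenter on the matched proposals to minimize worst deviation
        mset = set(matched)
        prop = [centers[k] for k in sorted(idx) if pairs[k] in mset]
        t_ref, _r = min_enclosing_ball(prop)
        idx2 = tree.query_ball_point(t_ref, tol + _EPS)
        matched2 = _max_one_to_one([pairs[k] for k in sorted(idx2)])
        if len(matched2) >= len(matched):
            t, matched = t_ref, matched2
        solutions.append(
            PlacementSolution(
                rotation=rotation,
                translation=np.asarray(t, dtype=float),
                matched_pairs=[
                    (
                        epi_sites[i],
                        loop_sites[j],
                        float(np.linalg.norm(epi_sites[i].position + t - loop_sites[j].position)),
                    )
                    for i, j in matched
                ],
            )
        )

    # merge near-duplicate placements, preferring more matches
    solutions.sort(
        key=lambda s: (-s.n_matches, s.translation[0], s.translation[1], s.translation[2])
    )
    kept: list[PlacementSolution] = []
    for sol in solutions:
        if any(
            np.linalg.norm(sol.translation - k.translation) < config.merge_tolerance
            for k in kept
        ):
            continue
        kept.append(sol)
    return kept


# ---------------------------------------------------------------------------
# Consistency, screening, completion, dedup
# ---------------------------------------------------------------------------


def _slot_of_loop(db: LoopDatabase, loop_id: str) -> int:
    for sid, loops in db.slots.items():
        if any(lp.loop_id == loop_id for lp in loops):
            return sid
    raise KeyError(loop_id)


def enforce_consistency(
    solution: PlacementSolution, db: LoopDatabase
) -> tuple[PlacementSolution, dict[int, Optional[str]]]:
    """Restrict matched pairs to one loop per slot and one rotamer per residue.

    Greedy: per slot keep the loop with the most matched pairs (ties by id);
    per (side, residue) keep the rotamer with the most pairs (ties by index).
    """
    pairs = solution.matched_pairs
    slot_loops: dict[int, dict[str, int]] = {}
    for _e, l, _d in pairs:
        sid = _slot_of_loop(db, l.source_loop)
        slot_loops.setdefault(sid, {}).setdefault(l.source_loop, 0)
        slot_loops[sid][l.source_loop] += 1
    chosen = {
        sid: max(sorted(counts), key=lambda lid: counts[lid])
        for sid, counts in slot_loops.items()
    }
    pairs = [p for p in pairs if p[1].source_loop == chosen[_slot_of_loop(db, p[1].source_loop)]]

    def pick_rotamers(side: int) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], dict[int, int]] = {}
        for p in pairs:
            s = p[side]
            key = (s.source_loop, s.residue_key)
            counts.setdefault(key, {}).setdefault(s.rotamer_index, 0)
            counts[key][s.rotamer_index] += 1
        return {
            key: max(sorted(rot), key=lambda r: rot[r]) for key, rot in counts.items()
        }

    for side in (0, 1):
        pick = pick_rotamers(side)
        pairs = [
            p for p in pairs
            if p[side].rotamer_index == pick[(p[side].source_loop, p[side].residue_key)]
        ]

    out = PlacementSolution(
        rotation=solution.rotation, translation=solution.translation, matched_pairs=pairs
    )
    loop_ids: dict[int, Optional[str]] = {sid: None for sid in db.slots}
    for sid, lid in chosen.items():
        loop_ids[sid] = lid
    return out, loop_ids


def _interacting_residue_keys(solution: PlacementSolution) -> set[tuple[str, str]]:
    """(source_loop, residue_key) of every residue forming a matched pair."""
    keys = set()
    for e, l, _d in solution.matched_pairs:
        keys.add((e.source_loop, e.residue_key))
        keys.add((l.source_loop, l.residue_key))
    return keys


def _eligible_atoms(model: StructureModel, interacting: set[str]) -> list:
    """Backbone atoms plus side-chain atoms of interacting residues."""
    out = []
    for res in model.residues():
        res_key = f"{res.chain_id}:{res.seq_id}:{res.res_name}"
        for a in res.atoms:
            if a.name in BACKBONE_ATOMS or res_key in interacting:
                out.append(a)
    return out


def screen_design(
    binder: StructureModel,
    placed_target: StructureModel,
    solution: PlacementSolution,
    loops: Sequence[LoopRecord],
    config: Optional[DesignConfig] = None,
) -> dict[str, bool]:
    """Verdicts for the three detrimental features.

    steric  - design-mode (80% vdW sum) clashes between binder and target,
              restricted to backbone atoms and side chains of residues that
              form the matched interactions (other side chains are assumed to
              repack); fails at >= steric_clash_limit.
    charge  - any like-charge pair within the charge-clash distance between
              binder and target or among the loops; fails at >= 1.
    positives - total Lys+Arg residues in the binding loops; fails above
              max_positive_loop_residues.
    """
    config = config or DesignConfig()
    interacting = {rk for _lp, rk in _interacting_residue_keys(solution)}
    binder_atoms = _eligible_atoms(binder, interacting)
    target_atoms = _eligible_atoms(placed_target, interacting)
    steric = count_clashes(binder_atoms, target_atoms, DESIGN_CLASH)

    charge = count_charge_clashes(
        list(binder.atoms()), list(placed_target.atoms()),
        distance=config.charge_clash_distance,
    )
    for la, lb in itertools.combinations(loops, 2):
        charge += count_charge_clashes(
            la.atoms(), lb.atoms(), distance=config.charge_clash_distance
        )

    positives = sum(lp.positive_residue_count() for lp in loops)
    return {
        "steric": steric < config.steric_clash_limit,
        "charge": charge == 0,
        "positives": positives <= config.max_positive_loop_residues,
    }


def assemble_binder(
    scaffold: StructureModel,
    specs: Sequence[AttachmentSpec],
    loops: Sequence[LoopRecord],
) -> StructureModel:
    """Loop-less scaffold plus designed loops, as one model."""
    bare = scaffold_without_loops(scaffold, specs)
    models = [bare]
    for k, lp in enumerate(loops):
        models.append(
            StructureModel(id=f"loop{lp.slot_id}", chains={"L": [r.copy() for r in lp.residues]})
        )
    return concatenate(models, new_id="binder")


def complete_design(
    partial: DesignCandidate,
    db: LoopDatabase,
    scaffold: StructureModel,
    specs: Sequence[AttachmentSpec],
    placed_target: StructureModel,
    config: Optional[DesignConfig] = None,
) -> list[DesignCandidate]:
    """Fill empty slots with database loops that keep the design clean.

    Candidate loops must be database-compatible with every selected loop and
    the augmented complex must still pass all screens.  Completions are
    enumerated deterministically (sorted loop ids) up to the configured cap.
    """
    config = config or DesignConfig()
    empty = [sid for sid, lid in partial.loop_ids.items() if lid is None]
    if not empty:
        return [partial]
    selected = [lid for lid in partial.loop_ids.values() if lid is not None]

    options: dict[int, list[str]] = {}
    for sid in empty:
        opts = [
            lp.loop_id
            for lp in sorted(db.slots[sid], key=lambda l: l.loop_id)
            if all(db.are_compatible(lp.loop_id, s) for s in selected)
        ]
        if not opts:
            logger.info("design %s: no compatible loop for slot %d", partial.design_id, sid)
            return []
        options[sid] = opts

    completions: list[DesignCandidate] = []
    for combo in itertools.product(*(options[sid] for sid in empty)):
        # cross-compatibility among the newly added loops themselves
        if any(
            not db.are_compatible(a, b) for a, b in itertools.combinations(combo, 2)
        ):
            continue
        loop_ids = dict(partial.loop_ids)
        for sid, lid in zip(empty, combo):
            loop_ids[sid] = lid
        loops = [db.loop(lid) for lid in loop_ids.values() if lid is not None]
        binder = assemble_binder(scaffold, specs, loops)
        verdicts = screen_design(binder, placed_target, partial.placement, loops, config)
        if all(verdicts.values()):
            completions.append(
                DesignCandidate(
                    design_id=f"{partial.design_id}+{'_'.join(combo)}",
                    loop_ids=loop_ids,
                    placement=partial.placement,
                    screening=verdicts,
                )
            )
            if len(completions) >= config.completion_cap:
                break
    return completions


def similarity(a: Sequence[Optional[str]], b: Sequence[Optional[str]]) -> float:
    """Fraction of slots holding the same loop ID."""
    if len(a) != len(b) or not a:
        raise ValueError("designs must have the same number of slots")
    shared = sum(1 for x, y in zip(a, b) if x is not None and x == y)
    return shared / len(a)


def dedupe_designs(
    designs: Sequence[DesignCandidate], threshold: float = 0.60
) -> list[DesignCandidate]:
    """Greedy pass in discovery order keeping designs <= threshold similar."""
    kept: list[DesignCandidate] = []
    for d in designs:
        if all(
            similarity(d.loop_id_tuple(), k.loop_id_tuple()) <= threshold for k in kept
        ):
            kept.append(d)
    return kept


# ---------------------------------------------------------------------------
# Repack and end-to-end driver
# ---------------------------------------------------------------------------


def repack_loops(
    loops: Sequence[LoopRecord],
    environment: StructureModel,
    interacting: set[tuple[str, str]],
    rotamers: RotamerSet,
) -> list[LoopRecord]:
    """Greedy rotamer substitution for clashing non-interacting side chains.

    For each loop residue whose side chain is not part of a matched
    interaction and clashes (design rule) with the environment, try the
    library rotamers and keep the conformation with the fewest clashes
    (native wins ties).  Backbones are never moved.
    """
    out = []
    env_atoms = [a for a in environment.atoms() if a.is_heavy]
    for lp in loops:
        new_residues = []
        for res in lp.residues:
            res_key = f"{res.chain_id}:{res.seq_id}:{res.res_name}"
            side = [a for a in res.atoms if a.name not in BACKBONE_ATOMS]
            if (
                (lp.loop_id, res_key) in interacting
                or not side
                or res.res_name not in rotamers.rotamers
                or not all(res.has_atom(n) for n in ("N", "CA", "C"))
            ):
                new_residues.append(res.copy())
                continue
            best = (count_clashes(side, env_atoms, DESIGN_CLASH), None)
            if best[0] > 0:
                for chis, _p in rotamers.for_residue(res.res_name):
                    rebuilt = place_sidechain(res, chis)
                    n = count_clashes(rebuilt, env_atoms, DESIGN_CLASH)
                    if n < best[0]:
                        best = (n, rebuilt)
            if best[1] is not None:
                r2 = res.copy()
                r2.atoms = [a for a in r2.atoms if a.name in BACKBONE_ATOMS] + best[1]
                new_residues.append(r2)
            else:
                new_residues.append(res.copy())
        out.append(
            LoopRecord(
                loop_id=lp.loop_id,
                slot_id=lp.slot_id,
                sequence=lp.sequence,
                residues=new_residues,
                signature=lp.signature,
                scaffold_clashes=lp.scaffold_clashes,
                scaffold_energy=lp.scaffold_energy,
            )
        )
    return out


def design_binders(
    target: StructureModel,
    epitope_selection: str | Sequence[Residue],
    db: LoopDatabase,
    scaffold: StructureModel,
    specs: Sequence[AttachmentSpec],
    config: Optional[DesignConfig] = None,
    params: Optional[EnergyParams] = None,
    rotamers: Optional[RotamerSet] = None,
) -> list[DesignCandidate]:
    """End-to-end design: orient, sweep, solve, screen, complete, dedupe, rank.

    Deterministic for identical inputs and configuration.  Returns candidates
    sorted by BE/BSA ascending (most favorable first).
    """
    config = config or DesignConfig()
    if db.n_loops() == 0:
        raise ValueError("empty loop database")
    rotamers = rotamers if rotamers is not None else load_packaged_rotamers()

    if isinstance(epitope_selection, str):
        epitope_residues = select_epitope(target, epitope_selection)
    else:
        epitope_residues = list(epitope_selection)
    oriented = orient_target(target, epitope_residues, config.epitope_height)
    epi_keys = {(r.chain_id, r.seq_id, r.insertion_code) for r in epitope_residues}
    oriented_epitope = [
        r for r in oriented.residues() if (r.chain_id, r.seq_id, r.insertion_code) in epi_keys
    ]

    loop_sites = [
        s for lid in sorted(db.interaction_sites) for s in db.interaction_sites[lid]
    ]

    candidates: list[DesignCandidate] = []
    n = 0
    for angle, esites in sweep_rotations(
        oriented, oriented_epitope, config,
        rotamers if config.epitope_rotamers else None,
    ):
        for sol in solve_translations(esites, loop_sites, config, rotation=angle):
            sol, loop_ids = enforce_consistency(sol, db)
            if sol.n_matches < config.min_interactions:
                continue
            placed = oriented.transform(rotation_about_z(angle), sol.translation)
            loops = [db.loop(lid) for lid in loop_ids.values() if lid is not None]
            binder = assemble_binder(scaffold, specs, loops)
            verdicts = screen_design(binder, placed, sol, loops, config)
            if not all(verdicts.values()):
                continue
            partial = DesignCandidate(
                design_id=f"d{n:05d}_r{angle:g}",
                loop_ids=loop_ids,
                placement=sol,
                screening=verdicts,
            )
            n += 1
            candidates.extend(
                complete_design(partial, db, scaffold, specs, placed, config)
            )

    candidates = dedupe_designs(candidates, config.similarity_threshold)

    # evaluation: repack clashing non-interacting side chains, then score
    for cand in candidates:
        placed = oriented.transform(
            rotation_about_z(cand.placement.rotation), cand.placement.translation
        )
        loops = [db.loop(lid) for lid in cand.loop_ids.values() if lid is not None]
        interacting = _interacting_residue_keys(cand.placement)
        bare = scaffold_without_loops(scaffold, specs)
        env = concatenate([bare, placed], new_id="env")
        loops = repack_loops(loops, env, interacting, rotamers)
        binder = assemble_binder(scaffold, specs, loops)
        cand.score = score_complex(binder, placed, params)

    def sort_key(c: DesignCandidate):
        bb = c.score.be_bsa if c.score and c.score.be_bsa is not None else float("inf")
        return (bb, c.design_id)

    return sorted(candidates, key=sort_key)
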