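"""Stage 1: harvest scaffold-compatible binding loops from a structure corpus.

A loop slot on the scaffold is defined by its two attachment-point residues
``i`` (immediately before the replaced range) and ``f`` (immediately after).
A candidate segment from the corpus matches a slot when the seven distances
between its own flanking residues - CAi-CAf, CBi-CBf, CAi-CBf, CBi-CAf,
Ni-Nf, Oi-Of, Ci-Cf - each agree with the scaffold's to within a tolerance
(0.225 Å by default; glycines use an ideally constructed virtual CB).

Matched loops are superposed onto the scaffold frame by a least-squares fit
of the eight flank backbone atoms, screened against the loop-less scaffold
(at most 16 heavy-atom clashes at the full vdW-sum rule and interaction
energy at most 237.5 kcal/mol) and pairwise against loops of other slots
(at most 3 clashes, at most 55.6 kcal/mol), and finally pruned so that every
retained loop has at least one compatible partner in every other slot.
"""

from __future__ import annotations

import csv
import hashlib
import io
import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .energetics import DATABASE_CLASH, EnergyParams, count_clashes, pair_energy
from .geometry import apply_rigid, kabsch
from .interaction_geometry import (
    InteractionSite,
    RotamerSet,
    enumerate_sites,
    load_packaged_rotamers,
)
from .structure_model import (
    Residue,
    StructureModel,
    read_structure,
    virtual_cbeta,
    write_structure,
)

logger = logging.getLogger(__name__)

DB_FORMAT_VERSION = 1

GEOMETRIC_TOLERANCE = 0.225        # Å, per-distance flank match tolerance
LOOP_SCAFFOLD_MAX_CLASHES = 16     # worst-decile CDR-vs-scaffold clash count
LOOP_SCAFFOLD_MAX_ENERGY = 237.5   # kcal/mol
LOOP_PAIR_MAX_CLASHES = 3          # worst-decile CDR-pair clash count
LOOP_PAIR_MAX_ENERGY = 55.6        # kcal/mol

SIGNATURE_KEYS = ("CAi_CAf", "CBi_CBf", "CAi_CBf", "CBi_CAf", "Ni_Nf", "Oi_Of", "Ci_Cf")
_FLANK_FIT_ATOMS = ("N", "CA", "C", "O")
_BOUNDARY_EPS = 1e-9  # float-noise guard so a deviation of exactly tol matches


@dataclass(frozen=True)
class AttachmentSpec:
    slot_id: int
    chain_id: str
    initial_residue: int            # seq id of residue i (precedes the loop)
    final_residue: int              # seq id of residue f (follows the loop)
    replaced_range: tuple[int, int]  # inclusive seq-id range the loop replaces

    def __post_init__(self) -> None:
        lo, hi = self.replaced_range
        if not (self.initial_residue < lo <= hi < self.final_residue):
            raise ValueError(
                f"slot {self.slot_id}: attachment residues must bracket the replaced range"
            )


@dataclass(frozen=True)
class GeometrySignature:
    distances: tuple[float, ...]  # ordered as SIGNATURE_KEYS

    def __post_init__(self) -> None:
        if len(self.distances) != 7:
            raise ValueError("signature needs exactly 7 distances")
        if any((not math.isfinite(d)) or d <= 0 for d in self.distances):
            raise ValueError("signature distances must be positive and finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SIGNATURE_KEYS, self.distances))


@dataclass
class LoopRecord:
    loop_id: str                 # source structure + chain + residue range
    slot_id: int
    sequence: str
    residues: list[Residue]      # all-atom loop residues in the scaffold frame
    signature: GeometrySignature
    scaffold_clashes: int = 0
    scaffold_energy: float = 0.0

    def atoms(self):
        return [a for r in self.residues for a in r.atoms]

    def positive_residue_count(self) -> int:
        return sum(1 for r in self.residues if r.res_name in ("LYS", "ARG"))


@dataclass
class LoopDatabase:
    slots: dict[int, list[LoopRecord]]
    compatibility: set[tuple[str, str]] = field(default_factory=set)
    interaction_sites: dict[str, list[InteractionSite]] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def loop(self, loop_id: str) -> LoopRecord:
        for loops in self.slots.values():
            for lp in loops:
                if lp.loop_id == loop_id:
                    return lp
        raise KeyError(f"loop {loop_id!r} not in database")

    def loop_ids(self) -> list[str]:
        return [lp.loop_id for loops in self.slots.values() for lp in loops]

    def are_compatible(self, a: str, b: str) -> bool:
        return (a, b) in self.compatibility or (b, a) in self.compatibility

    def n_loops(self) -> int:
        return sum(len(v) for v in self.slots.values())


def _residue_signature_points(res: Residue) -> dict[str, np.ndarray]:
    pts = {name: res.atom(name).coord for name in ("N", "CA", "C", "O")}
    pts["CB"] = virtual_cbeta(res)
    return pts


def signature_from_residues(res_i: Residue, res_f: Residue) -> GeometrySignature:
    """Seven flank distances between attachment residues i and f."""
    pi = _residue_signature_points(res_i)
    pf = _residue_signature_points(res_f)
    pairs = [
        ("CA", "CA"), ("CB", "CB"), ("CA", "CB"), ("CB", "CA"),
        ("N", "N"), ("O", "O"), ("C", "C"),
    ]
    return GeometrySignature(
        tuple(float(np.linalg.norm(pi[a] - pf[b])) for a, b in pairs)
    )


def scaffold_signature(scaffold: StructureModel, spec: AttachmentSpec) -> GeometrySignature:
    res_i = scaffold.residue(spec.chain_id, spec.initial_residue)
    res_f = scaffold.residue(spec.chain_id, spec.final_residue)
    for r in (res_i, res_f):
        if not r.has_backbone():
            raise KeyError(
                f"attachment residue {r.seq_id} is missing backbone atoms"
            )
    return signature_from_residues(res_i, res_f)


def match_candidate(
    candidate_sig: GeometrySignature,
    scaffold_sig: GeometrySignature,
    tolerance: float = GEOMETRIC_TOLERANCE,
) -> tuple[bool, dict[str, float]]:
    """Inclusive per-distance comparison; returns (match, deviations)."""
    deviations = {
        k: abs(c - s)
        for k, c, s in zip(SIGNATURE_KEYS, candidate_sig.distances, scaffold_sig.distances)
    }
    ok = all(d <= tolerance + _BOUNDARY_EPS for d in deviations.values())
    return ok, deviations


def _contiguous_runs(residues: Sequence[Residue]) -> list[list[Residue]]:
    """Split a chain into peptide-bonded runs (C_n - N_{n+1} < 2.0 Å)."""
    runs: list[list[Residue]] = []
    current: list[Residue] = []
    for res in residues:
        if not res.is_standard or not res.has_backbone():
            if current:
                runs.append(current)
            current = []
            continue
        if current:
            prev = current[-1]
            gap = float(np.linalg.norm(prev.atom("C").coord - res.atom("N").coord))
            if gap > 2.0:
                runs.append(current)
                current = []
        current.append(res)
    if current:
        runs.append(current)
    return runs


def _superpose_candidate(
    flank_i: Residue, flank_f: Residue, scaffold_i: Residue, scaffold_f: Residue
) -> tuple[np.ndarray, np.ndarray]:
    mobile = np.vstack([flank_i.coords(_FLANK_FIT_ATOMS), flank_f.coords(_FLANK_FIT_ATOMS)])
    reference = np.vstack(
        [scaffold_i.coords(_FLANK_FIT_ATOMS), scaffold_f.coords(_FLANK_FIT_ATOMS)]
    )
    return kabsch(mobile, reference)


def harvest_loops(
    corpus: Iterable[StructureModel],
    scaffold: StructureModel,
    specs: Sequence[AttachmentSpec],
    length_range: tuple[int, int] = (4, 20),
    tolerance: float = GEOMETRIC_TOLERANCE,
) -> dict[int, list[LoopRecord]]:
    """Search the corpus for loop segments matching each slot's flank geometry.

    Every contiguous candidate segment whose flanking residues match a slot
    signature is superposed onto the scaffold frame and recorded; retention is
    independent of the segment's original interface context.  Unreadable
    corpus entries are the caller's concern (see cli run drivers); here the
    corpus is already-parsed models.
    """
    lmin, lmax = length_range
    if lmin < 1 or lmax < lmin:
        raise ValueError("invalid loop length range")
    slot_sigs = {s.slot_id: scaffold_signature(scaffold, s) for s in specs}
    slot_res = {
        s.slot_id: (
            scaffold.residue(s.chain_id, s.initial_residue),
            scaffold.residue(s.chain_id, s.final_residue),
        )
        for s in specs
    }
    found: dict[int, list[LoopRecord]] = {s.slot_id: [] for s in specs}
    seen: set[tuple[int, str]] = set()

    for model in corpus:
        for chain_id, residues in model.chains.items():
            for run in _contiguous_runs(residues):
                n = len(run)
                for length in range(lmin, min(lmax, n - 2) + 1):
                    for start in range(1, n - length):
                        flank_i = run[start - 1]
                        flank_f = run[start + length]
                        cand_sig = signature_from_residues(flank_i, flank_f)
                        for slot_id, ref_sig in slot_sigs.items():
                            ok, _dev = match_candidate(cand_sig, ref_sig, tolerance)
                            if not ok:
                                continue
                            loop_id = (
                                f"{model.id}/{chain_id}/"
                                f"{run[start].seq_id}-{run[start + length - 1].seq_id}"
                            )
                            if (slot_id, loop_id) in seen:
                                continue
                            seen.add((slot_id, loop_id))
                            R, t = _superpose_candidate(
                                flank_i, flank_f, *slot_res[slot_id]
                            )
                            loop_res = []
                            for r in run[start:start + length]:
                                rc = r.copy()
                                rc.chain_id = _slot_chain_id(slot_id)
                                for a in rc.atoms:
                                    a.coord = apply_rigid(a.coord, R, t)
                                loop_res.append(rc)
                            found[slot_id].append(
                                LoopRecord(
                                    loop_id=loop_id,
                                    slot_id=slot_id,
                                    sequence="".join(r.one_letter for r in loop_res),
                                    residues=loop_res,
                                    signature=cand_sig,
                                )
                            )
    for slot_id in found:
        found[slot_id].sort(key=lambda lp: lp.loop_id)
    return found


def _slot_chain_id(slot_id: int) -> str:
    """Single-char chain id for designed loop residues (L, M, N, ...)."""
    return chr(ord("L") + (slot_id - 1) % 14)


def scaffold_without_loops(
    scaffold: StructureModel, specs: Sequence[AttachmentSpec]
) -> StructureModel:
    """Scaffold copy with every replaced loop range excised."""
    cut = scaffold.copy()
    for spec in specs:
        lo, hi = spec.replaced_range
        cut.chains[spec.chain_id] = [
            r for r in cut.chains[spec.chain_id]
            if not (lo <= r.seq_id <= hi)
        ]
    return cut


def _screening_context(
    scaffold: StructureModel, specs: Sequence[AttachmentSpec], slot_id: int
) -> StructureModel:
    """Loop-less scaffold minus the slot's own attachment residues.

    The attachment residues i and f become the loop's bonded neighbors after
    grafting, so their near-contact with the loop's terminal atoms is a bond,
    not an interaction; they are excluded from the clash/energy screen.
    """
    cut = scaffold_without_loops(scaffold, specs)
    spec = next(s for s in specs if s.slot_id == slot_id)
    cut.chains[spec.chain_id] = [
        r for r in cut.chains[spec.chain_id]
        if r.seq_id not in (spec.initial_residue, spec.final_residue)
    ]
    return cut


def screen_loop_vs_scaffold(
    loop: LoopRecord,
    scaffold_minus_loops: StructureModel,
    params: Optional[EnergyParams] = None,
    max_clashes: int = LOOP_SCAFFOLD_MAX_CLASHES,
    max_energy: float = LOOP_SCAFFOLD_MAX_ENERGY,
) -> tuple[bool, int, float]:
    clashes = count_clashes(loop.atoms(), scaffold_minus_loops, DATABASE_CLASH)
    energy = pair_energy(loop.atoms(), list(scaffold_minus_loops.atoms()), params)
    return clashes <= max_clashes and energy <= max_energy, clashes, energy


def screen_loop_pair(
    loop_a: LoopRecord,
    loop_b: LoopRecord,
    params: Optional[EnergyParams] = None,
    max_clashes: int = LOOP_PAIR_MAX_CLASHES,
    max_energy: float = LOOP_PAIR_MAX_ENERGY,
) -> tuple[bool, int, float]:
    if loop_a.slot_id == loop_b.slot_id:
        raise ValueError("loop pair screening requires loops from different slots")
    clashes = count_clashes(loop_a.atoms(), loop_b.atoms(), DATABASE_CLASH)
    energy = pair_energy(loop_a.atoms(), loop_b.atoms(), params)
    return clashes <= max_clashes and energy <= max_energy, clashes, energy


def prune_by_connectivity(db: LoopDatabase) -> LoopDatabase:
    """Iteratively drop loops lacking a compatible partner in some other slot."""
    slots = {sid: list(loops) for sid, loops in db.slots.items()}
    compat = set(db.compatibility)
    slot_of = {lp.loop_id: sid for sid, loops in slots.items() for lp in loops}

    def partners(loop_id: str) -> dict[int, int]:
        counts = {sid: 0 for sid in slots if sid != slot_of[loop_id]}
        for a, b in compat:
            if a == loop_id and b in slot_of:
                counts[slot_of[b]] = counts.get(slot_of[b], 0) + 1
            elif b == loop_id and a in slot_of:
                counts[slot_of[a]] = counts.get(slot_of[a], 0) + 1
        return counts

    changed = True
    while changed:
        changed = False
        for sid, loops in slots.items():
            keep = []
            for lp in loops:
                other = [s for s in slots if s != sid]
                cnt = partners(lp.loop_id)
                if all(cnt.get(s, 0) > 0 for s in other):
                    keep.append(lp)
                else:
                    changed = True
                    compat = {
                        (a, b) for a, b in compat if a != lp.loop_id and b != lp.loop_id
                    }
                    del slot_of[lp.loop_id]
            slots[sid] = keep
    for sid, loops in slots.items():
        if not loops:
            raise ValueError(f"no viable loops for slot {sid}")
    return LoopDatabase(
        slots=slots,
        compatibility=compat,
        interaction_sites={
            k: v for k, v in db.interaction_sites.items() if k in slot_of
        },
        parameters=dict(db.parameters),
    )


def combinatorial_diversity(db: LoopDatabase) -> int:
    """Product of per-slot loop counts (ignores pairwise compatibility)."""
    if not db.slots:
        raise ValueError("database has no slots")
    out = 1
    for loops in db.slots.values():
        out *= len(loops)
    return out


def build_database(
    corpus: Iterable[StructureModel],
    scaffold: StructureModel,
    specs: Sequence[AttachmentSpec],
    length_range: tuple[int, int] = (4, 20),
    tolerance: float = GEOMETRIC_TOLERANCE,
    params: Optional[EnergyParams] = None,
    rotamers: Optional[RotamerSet] = None,
    prune: bool = True,
) -> LoopDatabase:
    """Full stage-1 driver: harvest, screen, prune, and precompute sites."""
    rotamers = rotamers if rotamers is not None else load_packaged_rotamers()
    harvested = harvest_loops(corpus, scaffold, specs, length_range, tolerance)

    slots: dict[int, list[LoopRecord]] = {}
    for sid, loops in harvested.items():
        context = _screening_context(scaffold, specs, sid)
        kept = []
        for lp in loops:
            ok, clashes, energy = screen_loop_vs_scaffold(lp, context, params)
            if ok:
                lp.scaffold_clashes = clashes
                lp.scaffold_energy = energy
                kept.append(lp)
        slots[sid] = kept

    compat: set[tuple[str, str]] = set()
    sids = sorted(slots)
    for sa, sb in itertools.combinations(sids, 2):
        for la in slots[sa]:
            for lb in slots[sb]:
                ok, _c, _e = screen_loop_pair(la, lb, params)
                if ok:
                    compat.add((la.loop_id, lb.loop_id))

    db = LoopDatabase(
        slots=slots,
        compatibility=compat,
        parameters={
            "tolerance": tolerance,
            "length_range": list(length_range),
            "loop_scaffold_max_clashes": LOOP_SCAFFOLD_MAX_CLASHES,
            "loop_scaffold_max_energy": LOOP_SCAFFOLD_MAX_ENERGY,
            "loop_pair_max_clashes": LOOP_PAIR_MAX_CLASHES,
            "loop_pair_max_energy": LOOP_PAIR_MAX_ENERGY,
        },
    )
    if prune and len(sids) > 1:
        db = prune_by_connectivity(db)

    for lp in (l for loops in db.slots.values() for l in loops):
        db.interaction_sites[lp.loop_id] = enumerate_sites(
            lp.residues, rotamers=rotamers, source_loop=lp.loop_id
        )
    return db


# ---------------------------------------------------------------------------
# On-disk format: loops/*.pdb + compatibility.tsv + sites.tsv + manifest.yaml
# ---------------------------------------------------------------------------


def _loop_filename(loop_id: str, slot_id: int) -> str:
    digest = hashlib.sha1(loop_id.encode()).hexdigest()[:12]
    return f"slot{slot_id}_{digest}.pdb"


def save_database(db: LoopDatabase, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "loops").mkdir(parents=True, exist_ok=True)

    loop_index = []
    for sid in sorted(db.slots):
        for lp in db.slots[sid]:
            fname = _loop_filename(lp.loop_id, sid)
            model = StructureModel(id="LOOP", chains={"L": [r.copy() for r in lp.residues]})
            (out / "loops" / fname).write_text(write_structure(model))
            loop_index.append(
                {
                    "loop_id": lp.loop_id,
                    "slot_id": sid,
                    "file": fname,
                    "sequence": lp.sequence,
                    "signature": [round(d, 6) for d in lp.signature.distances],
                    "scaffold_clashes": lp.scaffold_clashes,
                    "scaffold_energy": round(lp.scaffold_energy, 6),
                }
            )

    compat_rows = sorted(db.compatibility)
    with (out / "compatibility.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["loop_a", "loop_b"])
        w.writerows(compat_rows)

    site_rows = 0
    with (out / "sites.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["loop_id", "residue", "rotamer", "family", "kind", "role",
             "group_atom", "x", "y", "z", "dx", "dy", "dz"]
        )
        for loop_id in sorted(db.interaction_sites):
            for s in db.interaction_sites[loop_id]:
                w.writerow(
                    [loop_id, s.residue_key, s.rotamer_index, s.family, s.kind,
                     s.role, s.group_atom]
                    + [f"{v:.6f}" for v in s.position]
                    + [f"{v:.6f}" for v in s.direction]
                )
                site_rows += 1

    manifest = {
        "format_version": DB_FORMAT_VERSION,
        "parameters": db.parameters,
        "slots": {sid: len(db.slots[sid]) for sid in sorted(db.slots)},
        "n_compatibility": len(compat_rows),
        "n_sites": site_rows,
        "loops": loop_index,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def load_database(in_dir: str | Path) -> LoopDatabase:
    src = Path(in_dir)
    manifest = yaml.safe_load((src / "manifest.yaml").read_text())
    if manifest.get("format_version") != DB_FORMAT_VERSION:
        raise ValueError(
            f"database format version {manifest.get('format_version')} "
            f"!= supported {DB_FORMAT_VERSION}"
        )

    slots: dict[int, list[LoopRecord]] = {int(s): [] for s in manifest["slots"]}
    for entry in manifest["loops"]:
        model = read_structure((src / "loops" / entry["file"]).read_text())
        residues = model.chains["L"]
        slots[int(entry["slot_id"])].append(
            LoopRecord(
                loop_id=entry["loop_id"],
                slot_id=int(entry["slot_id"]),
                sequence=entry["sequence"],
                residues=residues,
                signature=GeometrySignature(tuple(float(d) for d in entry["signature"])),
                scaffold_clashes=int(entry["scaffold_clashes"]),
                scaffold_energy=float(entry["scaffold_energy"]),
            )
        )
    for sid, expected in manifest["slots"].items():
        if len(slots[int(sid)]) != int(expected):
            raise ValueError(f"slot {sid}: loop count mismatch with manifest")

    compat: set[tuple[str, str]] = set()
    with (src / "compatibility.tsv").open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["loop_a", "loop_b"]:
            raise ValueError("compatibility.tsv: unexpected header")
        for row in reader:
            if len(row) != 2:
                raise ValueError("compatibility.tsv: malformed row")
            compat.add((row[0], row[1]))
    if len(compat) != int(manifest["n_compatibility"]):
        raise ValueError("compatibility.tsv is truncated or corrupt")

    sites: dict[str, list[InteractionSite]] = {}
    n_sites = 0
    with (src / "sites.tsv").open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if len(row) != 13:
                raise ValueError("sites.tsv: malformed row")
            (loop_id, residue_key, rot, family, kind, role, group_atom,
             x, y, z, dx, dy, dz) = row
            sites.setdefault(loop_id, []).append(
                InteractionSite(
                    position=np.array([float(x), float(y), float(z)]),
                    family=family,
                    kind=kind,
                    role=role,
                    direction=np.array([float(dx), float(dy), float(dz)]),
                    source_loop=loop_id,
                    residue_key=residue_key,
                    rotamer_index=int(rot),
                )
            )
            n_sites += 1
    if n_sites != int(manifest["n_sites"]):
        raise ValueError("sites.tsv is truncated or corrupt")

    return LoopDatabase(
        slots=slots,
        compatibility=compat,
        interaction_sites=sites,
        parameters=manifest.get("parameters", {}),
    )
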