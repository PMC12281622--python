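"""Deterministic synthetic inputs: scaffolds, loop corpora, rigged benchmarks.

Everything the pipeline consumes can be generated here offline: a miniature
multi-slot scaffold with an idealized walked backbone, corpora of candidate
structures containing planted geometric matches and perturbed decoys with
recorded ground-truth labels, ideal interaction-pair fixtures for every
interaction family, and a fully "rigged" benchmark whose loop database is
engineered to present complementary interaction sites for a toy epitope
(verified at generation time by running the matcher).

The fixtures use idealized backbone geometry (residues walked along smooth
polylines with ~1.33 Å peptide-bond steps) rather than fragments of real
structures, so the package ships no third-party data.  They are geometrically
consistent inputs, not physically realistic proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binder_design import DesignConfig, orient_target, screen_design, solve_translations
from .geometry import rotation_about_z, rotation_aligning, unit
from .interaction_geometry import (
    INTERACTION_SPECS,
    InteractionSite,
    enumerate_sites,
    place_sidechain,
)
from .loop_harvest import AttachmentSpec, GEOMETRIC_TOLERANCE, LoopDatabase, build_database
from .structure_model import Atom, Residue, StructureModel, make_atom

_PEPTIDE_STEP = (1.33, 1.46, 1.52)  # C->N, N->CA, CA->C advances along the path
_RESIDUE_SPAN = sum(_PEPTIDE_STEP)  # 4.31 Å of path consumed per residue


@dataclass
class FixtureSpec:
    seed: int = 0
    n_slots: int = 3
    n_planted: int = 5
    n_decoys: int = 20
    decoy_perturbation: float = 0.5   # Å, applied to one flank along the i-f axis
    epitope_sequence: str = "GDGGGGGGDG"
    rigged: bool = False


# ---------------------------------------------------------------------------
# Polyline-walked backbones
# ---------------------------------------------------------------------------


class _Polyline:
    def __init__(self, points: Sequence[np.ndarray]):
        self.pts = [np.asarray(p, dtype=float) for p in points]
        segs = [np.linalg.norm(b - a) for a, b in zip(self.pts, self.pts[1:])]
        self.cum = np.concatenate([[0.0], np.cumsum(segs)])

    @property
    def length(self) -> float:
        return float(self.cum[-1])

    def at(self, s: float) -> np.ndarray:
        s = min(max(s, 0.0), self.length)
        k = int(np.searchsorted(self.cum, s, side="right")) - 1
        k = min(k, len(self.pts) - 2)
        seg = self.cum[k + 1] - self.cum[k]
        frac = 0.0 if seg < 1e-12 else (s - self.cum[k]) / seg
        return self.pts[k] + frac * (self.pts[k + 1] - self.pts[k])

    def tangent(self, s: float) -> np.ndarray:
        h = 0.05
        a = self.at(max(0.0, s - h))
        b = self.at(min(self.length, s + h))
        return unit(b - a)


def _perp_direction(d: np.ndarray, prefer: np.ndarray) -> np.ndarray:
    p = prefer - np.dot(prefer, d) * d
    if np.linalg.norm(p) < 1e-6:
        p = np.array([0.0, 1.0, 0.0]) - d[1] * d
    return unit(p)


def _build_residue_on_path(
    path: _Polyline, s: float, res_name: str, seq_id: int, chain_id: str,
    o_prefer: np.ndarray,
) -> tuple[Residue, float]:
    """Place one residue consuming _RESIDUE_SPAN of path starting at arc s."""
    n_pos = path.at(s + _PEPTIDE_STEP[0])
    ca_pos = path.at(s + _PEPTIDE_STEP[0] + _PEPTIDE_STEP[1])
    c_pos = path.at(s + _RESIDUE_SPAN)
    d = path.tangent(s + _PEPTIDE_STEP[0] + _PEPTIDE_STEP[1])
    o_dir = _perp_direction(d, o_prefer)
    atoms = [
        make_atom("N", "N", n_pos, res_name),
        make_atom("CA", "C", ca_pos, res_name),
        make_atom("C", "C", c_pos, res_name),
        make_atom("O", "O", c_pos + 1.23 * o_dir, res_name),
    ]
    res = Residue(res_name=res_name, seq_id=seq_id, chain_id=chain_id, atoms=atoms)
    if res_name != "GLY":
        from .interaction_geometry import virtual_cbeta_ideal

        cb = virtual_cbeta_ideal(n_pos, ca_pos, c_pos)
        res.atoms.append(make_atom("CB", "C", cb, res_name))
    return res, s + _RESIDUE_SPAN


def chain_fillers(
    start_c: np.ndarray,
    end_n: np.ndarray,
    detour: np.ndarray,
    res_names: Optional[Sequence[str]] = None,
    extra_residues: int = 0,
    start_seq: int = 1,
    chain_id: str = "A",
    o_prefer: np.ndarray = np.array([0.0, 0.0, 1.0]),
) -> list[Residue]:
    """Chain idealized residues from an existing C atom to an existing N atom.

    The number of residues follows from the gap length (plus
    ``extra_residues``); the path bulges along ``detour`` so that its arc
    length leaves exactly one peptide-bond step (1.33 Å) after the last
    residue, keeping the whole stretch peptide-contiguous.
    """
    start_c = np.asarray(start_c, float)
    end_n = np.asarray(end_n, float)
    dvec = end_n - start_c
    dist = float(np.linalg.norm(dvec))
    k = max(0, math.ceil((dist - 1.4) / _RESIDUE_SPAN)) + extra_residues
    if k == 0:
        if dist > 2.0:
            raise ValueError("gap too large for a direct peptide bond")
        return []
    needed = _RESIDUE_SPAN * k + _PEPTIDE_STEP[0]
    half = dist / 2.0
    bulge = math.sqrt(max(0.0, (needed / 2.0) ** 2 - half ** 2))
    perp = _perp_direction(unit(dvec) if dist > 1e-9 else np.array([1.0, 0, 0]),
                           np.asarray(detour, float))
    mid = (start_c + end_n) / 2.0 + bulge * perp
    path = _Polyline([start_c, mid, end_n])
    names = list(res_names) if res_names else ["GLY"] * k
    if len(names) != k:
        raise ValueError(f"need {k} residue names, got {len(names)}")
    out = []
    s = 0.0
    for j in range(k):
        res, s = _build_residue_on_path(path, s, names[j], start_seq + j, chain_id, perp)
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Scaffold
# ---------------------------------------------------------------------------


def make_scaffold(spec: Optional[FixtureSpec] = None) -> tuple[StructureModel, list[AttachmentSpec]]:
    """Idealized multi-slot scaffold in the canonical frame.

    The backbone is walked along a polyline: a low lead-in strand, then for
    each slot a tall arc (the native binding loop, pointing +z) flanked by
    attachment residues at z ~ 0, connected by U-shaped body segments at
    negative y.  Slot flank separations and arc heights differ between slots
    so the seven-distance attachment signatures are well separated.  The
    attachment-point centroid is placed at the origin.
    """
    spec = spec or FixtureSpec()
    n_slots = spec.n_slots
    if n_slots < 1:
        raise ValueError("need at least one slot")

    pts: list[np.ndarray] = [np.array([-6.0, -9.0, 0.0]), np.array([-3.0, -3.0, 0.0])]
    loop_marks: list[tuple[float, float]] = []  # arc-length spans, filled after build
    mark_points: list[tuple[int, int]] = []     # indices into pts bracketing each loop
    x = 0.0
    for k in range(n_slots):
        chord = 6.0 + 1.5 * k
        apex = 11.0 + 1.0 * k
        pts.append(np.array([x, 0.0, 0.0]))
        i_idx = len(pts) - 1
        pts.append(np.array([x + chord / 2.0, 0.0, apex]))
        pts.append(np.array([x + chord, 0.0, 0.0]))
        f_idx = len(pts) - 1
        mark_points.append((i_idx, f_idx))
        pts.append(np.array([x + chord + 2.0, -7.0, 0.0]))
        pts.append(np.array([x + chord + 14.0, -7.0, 0.0]))
        x = x + chord + 16.0
    pts.append(np.array([x, -3.0, 0.0]))

    path = _Polyline(pts)
    for i_idx, f_idx in mark_points:
        loop_marks.append((float(path.cum[i_idx]), float(path.cum[f_idx])))

    residues: list[Residue] = []
    spans: list[tuple[float, float]] = []
    s = 0.0
    seq = 1
    while s + _RESIDUE_SPAN <= path.length:
        res, s2 = _build_residue_on_path(path, s, "ALA", seq, "A", np.array([0.0, 0.0, 1.0]))
        residues.append(res)
        spans.append((s, s2))
        s = s2
        seq += 1

    specs: list[AttachmentSpec] = []
    for slot_id, (s_lo, s_hi) in enumerate(loop_marks, start=1):
        inside = [r for r, (a, b) in zip(residues, spans) if a >= s_lo - 1e-6 and b <= s_hi + 1e-6]
        if len(inside) < 4:
            raise ValueError(f"slot {slot_id}: native loop too short; widen the arc")
        lo = inside[0].seq_id
        hi = inside[-1].seq_id
        for r in inside:
            r.res_name = "GLY"
            r.atoms = [a for a in r.atoms if a.name != "CB"]
        specs.append(
            AttachmentSpec(
                slot_id=slot_id,
                chain_id="A",
                initial_residue=lo - 1,
                final_residue=hi + 1,
                replaced_range=(lo, hi),
            )
        )

    model = StructureModel(id="toyscaffold", chains={"A": residues},
                           provenance="synthetic idealized scaffold")

    # center the attachment-point centroid at the origin
    anchors = []
    for sp in specs:
        anchors.append(model.residue("A", sp.initial_residue).atom("CA").coord)
        anchors.append(model.residue("A", sp.final_residue).atom("CA").coord)
    centroid = np.mean(anchors, axis=0)
    model = model.translate(-centroid)

    _assert_separated_signatures(model, specs)
    return model, specs


def _assert_separated_signatures(model: StructureModel, specs: Sequence[AttachmentSpec]) -> None:
    from .loop_harvest import match_candidate, scaffold_signature

    sigs = [scaffold_signature(model, sp) for sp in specs]
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            ok, _dev = match_candidate(sigs[i], sigs[j], tolerance=2 * GEOMETRIC_TOLERANCE)
            if ok:
                raise ValueError("slot signatures are not separated; adjust geometry")


# ---------------------------------------------------------------------------
# Loop corpus with planted matches and decoys
# ---------------------------------------------------------------------------


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    R = np.array(
        [
            [1 - 2 * (yq * yq + zq * zq), 2 * (xq * yq - zq * w), 2 * (xq * zq + yq * w)],
            [2 * (xq * yq + zq * w), 1 - 2 * (xq * xq + zq * zq), 2 * (yq * zq - xq * w)],
            [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w), 1 - 2 * (xq * xq + yq * yq)],
        ]
    )
    t = rng.uniform(-25.0, 25.0, size=3)
    return R, t


def _corpus_entry(
    entry_id: str,
    flank_i: Residue,
    flank_f: Residue,
    detour_angle: float,
    extra_residues: int,
    rng: np.random.Generator,
) -> tuple[StructureModel, tuple[int, int]]:
    """One corpus structure: [flank_i, routed interior, flank_f], renumbered,
    rigidly transformed.  Returns the model and the interior seq-id range."""
    fi = flank_i.copy()
    ff = flank_f.copy()
    axis = unit(ff.atom("CA").coord - fi.atom("CA").coord)
    base = np.array([0.0, 0.0, 1.0])
    # rotate the detour preference around the i->f axis for variety
    c, s = math.cos(detour_angle), math.sin(detour_angle)
    k = axis
    detour = base * c + np.cross(k, base) * s + k * np.dot(k, base) * (1 - c)
    interior = chain_fillers(
        fi.atom("C").coord, ff.atom("N").coord, detour,
        extra_residues=extra_residues, start_seq=2, chain_id="A",
    )
    fi.seq_id = 1
    ff.seq_id = 2 + len(interior)
    residues = [fi] + interior + [ff]
    for i, r in enumerate(residues, start=1):
        r.seq_id = i
        r.chain_id = "A"
    model = StructureModel(id=entry_id, chains={"A": residues})
    R, t = _random_rigid(rng)
    return model.transform(R, t), (2, 1 + len(interior))


def make_loop_corpus(
    spec: FixtureSpec,
    scaffold: StructureModel,
    attachment_specs: Sequence[AttachmentSpec],
    tolerance: float = GEOMETRIC_TOLERANCE,
) -> tuple[list[StructureModel], list[dict]]:
    """Corpus of planted matches and perturbed decoys with ground-truth labels.

    Planted entries copy the slot's flank residues exactly (so all seven
    attachment distances deviate by 0); decoys translate the f-flank along the
    i->f axis by ``decoy_perturbation``, which shifts the CAi-CAf distance by
    exactly that amount.  Raises if the perturbation does not exceed the
    matching tolerance (the labels would be wrong).
    """
    if spec.decoy_perturbation <= tolerance:
        raise ValueError("decoy perturbation must exceed the matching tolerance")
    rng = np.random.default_rng(spec.seed)
    corpus: list[StructureModel] = []
    labels: list[dict] = []
    for sp in attachment_specs:
        flank_i = scaffold.residue(sp.chain_id, sp.initial_residue)
        flank_f = scaffold.residue(sp.chain_id, sp.final_residue)
        axis = unit(flank_f.atom("CA").coord - flank_i.atom("CA").coord)
        for e in range(spec.n_planted):
            eid = f"pl_s{sp.slot_id}_{e}"
            # planted loops fan out within ±~50 deg of "up" so that, once
            # grafted, they arc away from the scaffold body like real loops
            angle = -0.9 + 1.8 * e / max(1, spec.n_planted - 1)
            model, (lo, hi) = _corpus_entry(
                eid, flank_i, flank_f,
                detour_angle=angle, extra_residues=3 + e % 3, rng=rng,
            )
            corpus.append(model)
            labels.append(
                {
                    "structure_id": eid,
                    "slot_id": sp.slot_id,
                    "kind": "planted",
                    "expected_loop_id": f"{eid}/A/{lo}-{hi}",
                }
            )
        for e in range(spec.n_decoys):
            eid = f"dc_s{sp.slot_id}_{e}"
            ff = flank_f.copy()
            for a in ff.atoms:
                a.coord = a.coord + spec.decoy_perturbation * axis
            model, _rng_range = _corpus_entry(
                eid, flank_i, ff,
                detour_angle=0.6 + 0.45 * e, extra_residues=3 + e % 4, rng=rng,
            )
            corpus.append(model)
            labels.append(
                {"structure_id": eid, "slot_id": sp.slot_id, "kind": "decoy",
                 "expected_loop_id": ""}
            )
    return corpus, labels


# ---------------------------------------------------------------------------
# Ideal interaction-pair fixtures (one per interaction family)
# ---------------------------------------------------------------------------

_TEMPLATE_BACKBONE = {
    "N": np.array([-0.52, 1.36, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.15, 1.05, 0.0]),
}

_TEMPLATE_CHIS = {
    "SER": (-65.0,), "ASN": (-65.0, -40.0), "ASP": (-70.0, -15.0),
    "GLU": (-67.0, 180.0, -10.0), "LYS": (-67.0, 180.0, 180.0, 180.0),
    "ARG": (-67.0, 180.0, 180.0, 180.0), "HIS": (-65.0, -70.0),
    "PHE": (-65.0, 90.0), "TYR": (-65.0, 90.0), "THR": (-60.0,),
}

FAMILY_FIXTURE_RESIDUES = {
    "hbond_NH_OC": ("LYS", "ASN"),
    "hbond_NH_OH": ("LYS", "SER"),
    "hbond_OH_OC": ("SER", "ASN"),
    "hbond_OH_OH": ("SER", "THR"),
    "salt_bridge_arg": ("ARG", "ASP"),
    "salt_bridge_lys": ("LYS", "ASP"),
    "cation_pi_arg": ("PHE", "ARG"),
    "cation_pi_lys": ("PHE", "LYS"),
    "pipi_parallel": ("PHE", "PHE"),
    "pipi_tshaped": ("PHE", "PHE"),
    "hispi_parallel": ("HIS", "PHE"),
    "hispi_tshaped": ("HIS", "PHE"),
}


def template_residue(res_name: str, seq_id: int = 1, chain_id: str = "A",
                     chis: Optional[Sequence[float]] = None) -> Residue:
    """A free-standing residue with an idealized backbone and side chain."""
    atoms = [make_atom(n, n[0], p.copy(), res_name) for n, p in _TEMPLATE_BACKBONE.items()]
    res = Residue(res_name=res_name, seq_id=seq_id, chain_id=chain_id, atoms=atoms)
    if res_name not in ("GLY", "ALA"):
        res.atoms.extend(place_sidechain(res, chis or _TEMPLATE_CHIS.get(res_name, ())))
    elif res_name == "ALA":
        from .interaction_geometry import virtual_cbeta_ideal

        cb = virtual_cbeta_ideal(*(res.atom(n).coord for n in ("N", "CA", "C")))
        res.atoms.append(make_atom("CB", "C", cb, res_name))
    return res


def _transform_residue(res: Residue, R: np.ndarray, t: np.ndarray) -> Residue:
    out = res.copy()
    for a in out.atoms:
        a.coord = a.coord @ np.asarray(R).T + np.asarray(t)
    return out


def make_interaction_pair(family: str, offset: float = 0.0) -> tuple[Residue, Residue]:
    """Two residues realizing one interaction family at its ideal geometry.

    Residue A emits the projection site; residue B is placed so its anchor
    group sits exactly at the projection position (displaced by ``offset`` Å
    along the projection axis), with the secondary constraint satisfied.
    """
    if family not in INTERACTION_SPECS:
        raise KeyError(f"unknown interaction family {family!r}")
    spec = INTERACTION_SPECS[family]
    name_a, name_b = FAMILY_FIXTURE_RESIDUES[family]
    res_a = template_residue(name_a, seq_id=1)
    sites_a = [
        s for s in enumerate_sites([res_a], rotamers=None, include_backbone=False)
        if s.family == family and s.kind == "projection"
    ]
    if not sites_a:
        raise ValueError(f"{name_a} emits no {family} projection")
    proj = sites_a[0]

    res_b0 = template_residue(name_b, seq_id=2)
    anchors = [
        s for s in enumerate_sites([res_b0], rotamers=None, include_backbone=False)
        if s.family == family and s.kind == "anchor"
    ]
    if not anchors:
        raise ValueError(f"{name_b} has no {family} anchor")
    anchor = anchors[0]

    if spec.secondary == "head_on":
        desired_axis = -proj.direction
    elif spec.secondary == "parallel_planes":
        desired_axis = proj.direction
    else:  # perpendicular_planes
        desired_axis = _perp_direction(proj.direction, np.array([0.0, 1.0, 0.3]))
    R = rotation_aligning(anchor.direction, desired_axis)
    target_pos = proj.position + offset * proj.direction
    t = target_pos - anchor.position @ R.T
    res_b = _transform_residue(res_b0, R, t)
    return res_a, res_b


# ---------------------------------------------------------------------------
# Rigged end-to-end benchmark
# ---------------------------------------------------------------------------


@dataclass
class RiggedBenchmark:
    scaffold: StructureModel
    attachment_specs: list[AttachmentSpec]
    database: LoopDatabase
    target: StructureModel
    epitope_selection: str
    config: DesignConfig
    n_planted_interactions: int = 4


def _strand(
    sequence: str, origin: np.ndarray, chain_id: str, o_dir: np.ndarray,
    cb_dir: np.ndarray, start_seq: int = 1, spacing: float = 3.6,
) -> list[Residue]:
    """Straight idealized strand along +x with explicit O and CB directions."""
    out = []
    from .interaction_geometry import SIDECHAIN_TOPOLOGY

    aa1to3 = {"G": "GLY", "A": "ALA", "D": "ASP", "K": "LYS", "S": "SER",
              "N": "ASN", "E": "GLU", "T": "THR", "Y": "TYR", "F": "PHE"}
    for j, letter in enumerate(sequence):
        res_name = aa1to3[letter]
        ca = origin + np.array([spacing * j, 0.0, 0.0])
        n_pos = ca + np.array([-1.2, 0.35, 0.0])
        c_pos = ca + np.array([1.25, 0.35, 0.0])
        atoms = [
            make_atom("N", "N", n_pos, res_name),
            make_atom("CA", "C", ca, res_name),
            make_atom("C", "C", c_pos, res_name),
            make_atom("O", "O", c_pos + 1.23 * unit(o_dir), res_name),
        ]
        res = Residue(res_name=res_name, seq_id=start_seq + j, chain_id=chain_id, atoms=atoms)
        if res_name != "GLY":
            cb = ca + 1.53 * unit(cb_dir + np.array([0.25, 0.0, 0.0]))
            res.atoms.append(make_atom("CB", "C", cb, res_name))
            if res_name in SIDECHAIN_TOPOLOGY and res_name != "ALA":
                # extend the side chain "downward": chi1 trans w.r.t. N
                res.atoms = [a for a in res.atoms if a.name != "CB"]
                res.atoms.extend(place_sidechain(res, (180.0, 0.0, 0.0, 0.0)))
        out.append(res)
    return out


def _make_toy_target(spec: FixtureSpec) -> tuple[StructureModel, str]:
    """Toy target: an epitope strand (chain T) under a body strand (chain U)."""
    n = len(spec.epitope_sequence)
    epi = _strand(
        spec.epitope_sequence, np.array([0.0, 0.0, 0.0]), "T",
        o_dir=np.array([0.0, -0.4, -1.0]), cb_dir=np.array([0.0, 0.3, -1.0]),
    )
    body = _strand("A" * n, np.array([0.0, 0.6, 4.5]), "U",
                   o_dir=np.array([0.0, 0.0, 1.0]), cb_dir=np.array([0.0, 0.0, 1.0]))
    model = StructureModel(id="toytarget", chains={"T": epi, "U": body})
    return model, f"T:1-{n}"


_ENG_TEMPLATES = {
    # residue, chis, axis atoms (tail -> head), head atom, family it donates
    "SER": ((-65.0,), ("CB", "OG"), "OG"),
    "LYS": ((-67.0, -68.0, 180.0, 180.0), ("CE", "NZ"), "NZ"),
}


def _engineer_donor_residue(
    res_name: str,
    anchor: InteractionSite,
    family: str,
    obstacles: np.ndarray,
    seq_id: int,
) -> Residue:
    """Place a donor residue so its projected ideal site hits ``anchor``.

    The donor axis is anti-aligned with the anchor's outward axis (head-on),
    the head atom sits at ideal distance along that axis, and the remaining
    spin about the axis is chosen to maximize clearance from ``obstacles``.
    """
    chis, (tail_name, head_name), head = _ENG_TEMPLATES[res_name]
    dist = INTERACTION_SPECS[family].ideal_distance
    template = template_residue(res_name, seq_id=seq_id, chis=chis)
    head_pos = template.atom(head).coord
    axis_t = unit(head_pos - template.atom(tail_name).coord)

    u = -unit(anchor.direction)              # donor axis points at the anchor
    head_target = anchor.position - dist * u
    R0 = rotation_aligning(axis_t, u)

    best: tuple[float, Residue] | None = None
    for k in range(24):
        phi = 15.0 * k
        Rspin = _axis_rotation(u, phi)
        R = Rspin @ R0
        t = head_target - head_pos @ R.T
        placed = _transform_residue(template, R, t)
        coords = np.array([a.coord for a in placed.atoms])
        if obstacles.size:
            d = np.linalg.norm(coords[:, None, :] - obstacles[None, :, :], axis=2)
            clearance = float(d.min())
        else:
            clearance = 99.0
        zmin = float(coords[:, 2].min())
        score = min(clearance, 3.2) + min(zmin, 0.0)  # prefer clear and above ground
        if best is None or score > best[0]:
            best = (score, placed)
    assert best is not None
    return best[1]


def _axis_rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = unit(axis)
    th = math.radians(degrees)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def _engineered_loop_entry(
    entry_id: str,
    flank_i: Residue,
    flank_f: Residue,
    engineered: list[Residue],
    detour: np.ndarray,
    extra_residues: int = 0,
) -> StructureModel:
    """Corpus entry whose interior passes through engineered residues."""
    fi = flank_i.copy()
    ff = flank_f.copy()
    pieces: list[Residue] = [fi]
    prev_c = fi.atom("C").coord
    for eng in engineered:
        pieces.extend(chain_fillers(prev_c, eng.atom("N").coord, detour, chain_id="A"))
        pieces.append(eng.copy())
        prev_c = eng.atom("C").coord
    pieces.extend(
        chain_fillers(prev_c, ff.atom("N").coord, detour, chain_id="A",
                      extra_residues=extra_residues)
    )
    pieces.append(ff)
    for i, r in enumerate(pieces, start=1):
        r.seq_id = i
        r.chain_id = "A"
    return StructureModel(id=entry_id, chains={"A": pieces})


def make_rigged_benchmark(spec: Optional[FixtureSpec] = None) -> RiggedBenchmark:
    """Scaffold + loop database + toy target guaranteed to be designable.

    Four donor residues (one Lys salt bridge, three Ser hydroxyl donors by
    default) are engineered into the slot-1 and slot-2 loops so their
    projected ideal-interaction sites coincide exactly with anchor sites on
    the canonically oriented toy epitope; slot 3 holds an inert loop that must
    be filled by the completion step.  The guarantee is checked at generation
    time by running the orientation, matching, and screening machinery; a
    construction that fails verification raises instead of returning.
    """
    spec = spec or FixtureSpec(rigged=True)
    config = DesignConfig(epitope_height=13.0)
    scaffold, specs = make_scaffold(spec)
    if len(specs) < 3:
        raise ValueError("rigged benchmark needs three slots")

    target0, epitope_sel = _make_toy_target(spec)
    from .binder_design import select_epitope

    epi_res0 = select_epitope(target0, epitope_sel)
    oriented = orient_target(target0, epi_res0, config.epitope_height)
    epi_keys = {(r.chain_id, r.seq_id) for r in epi_res0}
    oriented_epi = [r for r in oriented.residues() if (r.chain_id, r.seq_id) in epi_keys]

    # native-conformation anchor sites on the canonical epitope
    sites = enumerate_sites(oriented_epi, rotamers=None, include_backbone=True)
    carbox = [s for s in sites if s.kind == "anchor" and s.family == "salt_bridge_lys"]
    carbonyl = [s for s in sites if s.kind == "anchor" and s.family == "hbond_OH_OC"
                and s.direction[2] < -0.3]

    if not carbox or len(carbonyl) < 3:
        raise ValueError("toy epitope exposes too few downward-facing anchors")

    # anchors are split into a left cluster (slot-1 loop: Lys salt bridge plus
    # one Ser H-bond) and a right cluster (slot-2 loop: two Ser H-bonds), so
    # the two engineered loops stay well apart
    def pick_spread(cands: list[InteractionSite], n: int, taken: list[np.ndarray],
                    min_sep: float = 4.0) -> list[InteractionSite]:
        chosen: list[InteractionSite] = []
        for s in cands:
            if all(np.linalg.norm(s.position - p) >= min_sep for p in taken):
                chosen.append(s)
                taken.append(s.position)
                if len(chosen) == n:
                    return chosen
        raise ValueError("could not select well-separated anchor sites")

    taken: list[np.ndarray] = []
    a_salt = pick_spread(sorted(carbox, key=lambda s: -s.position[0]), 1, taken)[0]
    right = [s for s in carbonyl if s.position[0] > a_salt.position[0]]
    left = [s for s in carbonyl if s.position[0] < a_salt.position[0] - 8.0]
    a_right = pick_spread(sorted(right, key=lambda s: -s.position[0]), 1, taken)[0]
    a_left = pick_spread(sorted(left, key=lambda s: s.position[0]), 2, taken)

    scaffold_coords = np.array([a.coord for a in scaffold.heavy_atoms()])
    target_coords = np.array([a.coord for a in oriented.heavy_atoms()])
    obstacles = np.vstack([scaffold_coords, target_coords])

    loop1_eng = [
        _engineer_donor_residue("SER", a_left[0], "hbond_OH_OC", obstacles, 0),
        _engineer_donor_residue("SER", a_left[1], "hbond_OH_OC", obstacles, 0),
    ]
    loop1_eng.sort(key=lambda r: r.atom("CA").coord[0])
    loop2_eng = [
        _engineer_donor_residue("LYS", a_salt, "salt_bridge_lys", obstacles, 0),
        _engineer_donor_residue("SER", a_right, "hbond_OH_OC", obstacles, 0),
    ]
    loop2_eng.sort(key=lambda r: r.atom("CA").coord[0])

    def flanks(sp: AttachmentSpec) -> tuple[Residue, Residue]:
        return (
            scaffold.residue(sp.chain_id, sp.initial_residue),
            scaffold.residue(sp.chain_id, sp.final_residue),
        )

    fi1, ff1 = flanks(specs[0])
    fi2, ff2 = flanks(specs[1])
    fi3, ff3 = flanks(specs[2])
    up = np.array([0.0, 1.2, 1.0])
    corpus = [
        _engineered_loop_entry("rig1", fi1, ff1, loop1_eng, up),
        _engineered_loop_entry("rig2", fi2, ff2, loop2_eng, up),
        _engineered_loop_entry("rig3", fi3, ff3, [], np.array([0.0, 0.8, 1.0]),
                               extra_residues=4),
    ]

    db = build_database(corpus, scaffold, specs)
    for sid in (1, 2, 3):
        if not db.slots.get(sid):
            raise ValueError(f"rigged benchmark: slot {sid} loop failed screening")

    # --- generation-time verification: run the matcher at rotation 0 ---
    from .interaction_geometry import epitope_sites as epi_sites_fn

    esites = epi_sites_fn(oriented, oriented_epi, rotamers=None)
    loop_sites = [s for lid in sorted(db.interaction_sites) for s in db.interaction_sites[lid]]
    sols = solve_translations(esites, loop_sites, config, rotation=0.0)
    good = [s for s in sols if s.n_matches >= config.min_interactions
            and np.linalg.norm(s.translation) < 0.5]
    if not good:
        raise ValueError("rigged benchmark verification failed: no planted placement found")

    return RiggedBenchmark(
        scaffold=scaffold,
        attachment_specs=list(specs),
        database=db,
        target=target0,
        epitope_selection=epitope_sel,
        config=config,
        n_planted_interactions=4,
    )
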