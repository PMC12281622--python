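"""Ideal-interaction geometry: rotamers, side-chain building, and sites.

The design strategy searches for "exceptional" (near-thermodynamic-optimum)
contacts: hydrogen bonds, salt bridges, cation-π and π-π interactions, each
with a literature-derived ideal distance and at least one secondary angular
constraint.  Around every binding-loop residue (and every epitope residue) we
enumerate :class:`InteractionSite` objects of two kinds:

* ``projection`` - a point in space at the ideal distance from an emitting
  group where the partner's key atom (or ring center) should sit;
* ``anchor`` - the key atom / ring center of a group that can serve as that
  partner.

Two sites are complementary when they belong to the same interaction family,
one is a projection and the other an anchor, and their stored direction
vectors satisfy the family's secondary constraint (a configurable angular
cone, 20° by default).  A geometric match then simply requires the projection
point and the anchor point to coincide within the match tolerance.

Side chains are rebuilt at library rotamers with a NeRF (natural-extension
reference frame) chain construction from ideal internal coordinates; only the
native residue type is ever used (the method does not mutate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .geometry import angle_between, nerf, unit, dihedral
from .structure_model import Residue, make_atom, virtual_cbeta, Atom

# ---------------------------------------------------------------------------
# Interaction family table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionSpec:
    family: str
    description: str
    ideal_distance: float
    projection_from: str
    anchor: str
    secondary: str
    horizontal_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.ideal_distance <= 0:
            raise ValueError("ideal distance must be positive")


def _load_interaction_specs() -> tuple[dict[str, InteractionSpec], float]:
    with resources.files("petei.data").joinpath("interactions.yaml").open("r") as fh:
        raw = yaml.safe_load(fh)
    specs = {
        name: InteractionSpec(
            family=name,
            description=row["description"],
            ideal_distance=float(row["distance"]),
            projection_from=row["projection_from"],
            anchor=row["anchor"],
            secondary=row["secondary"],
            horizontal_offset=float(row.get("horizontal_offset", 0.0)),
        )
        for name, row in raw["families"].items()
    }
    return specs, float(raw["secondary_cone_deg"])


INTERACTION_SPECS, DEFAULT_SECONDARY_CONE = _load_interaction_specs()


@dataclass
class InteractionSite:
    position: np.ndarray          # where the partner key atom / this anchor sits
    family: str
    kind: str                     # "projection" | "anchor"
    role: str                     # donor | acceptor | cation | anion | ring
    direction: np.ndarray         # emitting-group axis / ring normal (unit)
    source_loop: str = ""         # loop_id or "" for epitope sites
    residue_key: str = ""         # e.g. "A:12:LYS"
    rotamer_index: int = 0        # 0 = native conformation
    group_atom: str = ""          # emitting/anchoring atom or ring label

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("site position must be finite")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "InteractionSite":
        s = InteractionSite(
            position=self.position @ np.asarray(R).T + np.asarray(t),
            family=self.family,
            kind=self.kind,
            role=self.role,
            direction=self.direction @ np.asarray(R).T,
            source_loop=self.source_loop,
            residue_key=self.residue_key,
            rotamer_index=self.rotamer_index,
            group_atom=self.group_atom,
        )
        return s


# ---------------------------------------------------------------------------
# Rotamers
# ---------------------------------------------------------------------------


@dataclass
class RotamerSet:
    """Per-residue lists of side-chain dihedral tuples with probabilities."""

    rotamers: dict[str, list[tuple[tuple[float, ...], float]]]

    def __post_init__(self) -> None:
        for res, rows in self.rotamers.items():
            for chis, _p in rows:
                for chi in chis:
                    if not (-180.0 < chi <= 180.0):
                        raise ValueError(f"{res}: dihedral {chi} outside (-180, 180]")

    def for_residue(self, res_name: str) -> list[tuple[tuple[float, ...], float]]:
        return self.rotamers.get(res_name, [])


def load_packaged_rotamers() -> RotamerSet:
    with resources.files("petei.data").joinpath("rotamers.yaml").open("r") as fh:
        raw = yaml.safe_load(fh)
    return RotamerSet(
        {
            res: [(tuple(float(c) for c in row["chis"]), float(row["prob"])) for row in rows]
            for res, rows in raw["rotamers"].items()
        }
    )


def load_rotamer_table(text: str) -> RotamerSet:
    """Parse a Dunbrack-style whitespace table.

    Expected columns per line: ``RES chi1 [chi2 chi3 chi4] prob``; lines
    starting with ``#`` are comments.  This is an interface for user-supplied
    libraries; no library is redistributed with the package.
    """
    table: dict[str, list[tuple[tuple[float, ...], float]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"rotamer table line {lineno}: need RES chi... prob")
        res = parts[0].upper()
        try:
            values = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"rotamer table line {lineno}: non-numeric field") from exc
        raw_chis, prob = values[:-1], values[-1]
        chis = []
        for c in raw_chis:
            wrapped = ((c + 180.0) % 360.0) - 180.0
            chis.append(180.0 if wrapped == -180.0 else wrapped)
        table.setdefault(res, []).append((tuple(chis), prob))
    return RotamerSet(table)


# ---------------------------------------------------------------------------
# Side-chain topology (ideal internal coordinates)
# ---------------------------------------------------------------------------

# Each entry: (atom, element, (ref_a, ref_b, ref_c), bond, angle, dihedral)
# where dihedral is ("chi", k, offset_deg) or ("fix", value_deg); the dihedral
# is measured over ref_a-ref_b-ref_c-atom.  CB is placed first from the
# backbone (ideal tetrahedral construction) and is common to all entries.
_T = {
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 120.0)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 120.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3, 0.0)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, ("fix", 0.0)),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, ("fix", 180.0)),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", "N", ("CA", "CB", "CG"), 1.371, 122.7, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.0, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.319, 109.3, ("fix", 180.0)),
        ("NE2", "N", ("CG", "ND1", "CE1"), 1.374, 111.7, ("fix", 0.0)),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.384, 120.8, ("fix", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.384, 120.8, ("fix", 180.0)),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.384, 120.0, ("fix", 0.0)),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.384, 120.8, ("fix", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.384, 120.8, ("fix", 180.0)),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.384, 120.0, ("fix", 0.0)),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fix", 180.0)),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 2, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, ("fix", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, ("fix", 180.0)),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, ("fix", 0.0)),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, ("fix", 180.0)),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.392, 118.7, ("fix", 180.0)),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, ("fix", 180.0)),
    ],
}

SIDECHAIN_TOPOLOGY = _T
ROTATABLE_RESIDUES = {r for r, steps in _T.items() if any(s[5][0] == "chi" for s in steps)}

N_CHI = {
    res: max((s[5][1] for s in steps if s[5][0] == "chi"), default=0)
    for res, steps in _T.items()
}

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
HIS_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")


def native_chis(residue: Residue) -> Optional[tuple[float, ...]]:
    """Side-chain dihedrals as recorded in the structure; None if incomplete."""
    res = residue.res_name
    if res not in _T:
        return None
    chis: list[float] = []
    coords = {a.name: a.coord for a in residue.atoms}
    if "CB" not in coords:
        coords["CB"] = virtual_cbeta(residue)
    for step in _T[res]:
        name, _el, refs, _b, _ang, dspec = step
        if dspec[0] != "chi":
            continue
        k = dspec[1]
        if dspec[2] != 0.0:
            continue  # only the defining branch of each chi
        if len(chis) >= k:
            continue
        if name not in coords or any(r not in coords for r in refs):
            return None
        chis.append(dihedral(coords[refs[0]], coords[refs[1]], coords[refs[2]], coords[name]))
    return tuple(chis)


def place_sidechain(residue: Residue, chis: Sequence[float]) -> list[Atom]:
    """Rebuild the side chain at the given dihedrals; backbone untouched.

    Returns the rebuilt side-chain atoms (CB onward).  Glycine returns an
    empty list.  Raises for residue types without a topology entry.
    """
    res = residue.res_name
    if res == "GLY":
        return []
    if res not in _T:
        raise KeyError(f"no side-chain topology for residue type {res!r}")
    for name in ("N", "CA", "C"):
        if not residue.has_atom(name):
            raise KeyError(f"{res} {residue.seq_id}: missing backbone atom {name}")
    need = N_CHI[res]
    if len(chis) < need:
        raise ValueError(f"{res} needs {need} dihedrals, got {len(chis)}")

    coords: dict[str, np.ndarray] = {
        "N": residue.atom("N").coord,
        "CA": residue.atom("CA").coord,
        "C": residue.atom("C").coord,
    }
    coords["CB"] = virtual_cbeta_ideal(coords["N"], coords["CA"], coords["C"])
    out = [make_atom("CB", "C", coords["CB"], res)]
    for name, element, refs, bond, ang, dspec in _T[res]:
        if dspec[0] == "chi":
            value = chis[dspec[1] - 1] + dspec[2]
        else:
            value = dspec[1]
        pos = nerf(coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, ang, value)
        coords[name] = pos
        out.append(make_atom(name, element, pos, res))
    return out


def virtual_cbeta_ideal(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    direction = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return ca + 1.53 * unit(direction)


# ---------------------------------------------------------------------------
# Functional groups and site emission
# ---------------------------------------------------------------------------


@dataclass
class _Group:
    """A chemical group with a key position and an outward axis."""

    kind: str        # NH_donor | OH_donor | carbonyl_O | hydroxyl_O |
                     # carboxylate_C | lys_cation | arg_cation |
                     # aromatic_ring | his_ring
    position: np.ndarray
    axis: np.ndarray
    label: str


def _ring_center_normal(coords: dict[str, np.ndarray], names: Sequence[str]):
    pts = np.array([coords[n] for n in names])
    center = pts.mean(axis=0)
    centered = pts - center
    _u, _s, vt = np.linalg.svd(centered)
    normal = unit(vt[2])
    return center, normal


def _residue_groups(
    residue: Residue,
    coords: dict[str, np.ndarray],
    prev_c: Optional[np.ndarray],
    include_backbone: bool = True,
) -> list[_Group]:
    """Enumerate donor/acceptor/cation/anion/ring groups of one residue.

    ``coords`` maps atom name to position (side chain possibly rebuilt at a
    rotamer).  Donor hydrogens are implicit: the donor axis points along the
    inferred heavy-atom geometry (amide-H bisector for backbone N-H; bond
    extension for side-chain donors).
    """
    res = residue.res_name
    groups: list[_Group] = []

    if include_backbone:
        if res != "PRO" and prev_c is not None and "N" in coords and "CA" in coords:
            n = coords["N"]
            h_dir = -(unit(coords["CA"] - n) + unit(prev_c - n))
            if np.linalg.norm(h_dir) > 1e-6:
                groups.append(_Group("NH_donor", n, unit(h_dir), "N"))
        if "C" in coords and "O" in coords:
            groups.append(_Group("carbonyl_O", coords["O"], unit(coords["O"] - coords["C"]), "O"))

    def have(*names: str) -> bool:
        return all(n in coords for n in names)

    if res == "SER" and have("CB", "OG"):
        ax = unit(coords["OG"] - coords["CB"])
        groups.append(_Group("OH_donor", coords["OG"], ax, "OG"))
        groups.append(_Group("hydroxyl_O", coords["OG"], ax, "OG"))
    if res == "THR" and have("CB", "OG1"):
        ax = unit(coords["OG1"] - coords["CB"])
        groups.append(_Group("OH_donor", coords["OG1"], ax, "OG1"))
        groups.append(_Group("hydroxyl_O", coords["OG1"], ax, "OG1"))
    if res == "TYR" and have("CZ", "OH"):
        ax = unit(coords["OH"] - coords["CZ"])
        groups.append(_Group("OH_donor", coords["OH"], ax, "OH"))
        groups.append(_Group("hydroxyl_O", coords["OH"], ax, "OH"))
    if res == "ASN" and have("CG", "OD1", "ND2"):
        groups.append(_Group("carbonyl_O", coords["OD1"], unit(coords["OD1"] - coords["CG"]), "OD1"))
        groups.append(_Group("NH_donor", coords["ND2"], unit(coords["ND2"] - coords["CG"]), "ND2"))
    if res == "GLN" and have("CD", "OE1", "NE2"):
        groups.append(_Group("carbonyl_O", coords["OE1"], unit(coords["OE1"] - coords["CD"]), "OE1"))
        groups.append(_Group("NH_donor", coords["NE2"], unit(coords["NE2"] - coords["CD"]), "NE2"))
    if res == "TRP" and have("CD1", "NE1"):
        groups.append(_Group("NH_donor", coords["NE1"], unit(coords["NE1"] - coords["CD1"]), "NE1"))
    if res == "ASP" and have("CB", "CG", "OD1", "OD2"):
        ax = unit(coords["CG"] - coords["CB"])
        groups.append(_Group("carboxylate_C", coords["CG"], ax, "CG"))
        for o in ("OD1", "OD2"):
            groups.append(_Group("carbonyl_O", coords[o], unit(coords[o] - coords["CG"]), o))
    if res == "GLU" and have("CG", "CD", "OE1", "OE2"):
        ax = unit(coords["CD"] - coords["CG"])
        groups.append(_Group("carboxylate_C", coords["CD"], ax, "CD"))
        for o in ("OE1", "OE2"):
            groups.append(_Group("carbonyl_O", coords[o], unit(coords[o] - coords["CD"]), o))
    if res == "LYS" and have("CE", "NZ"):
        ax = unit(coords["NZ"] - coords["CE"])
        groups.append(_Group("lys_cation", coords["NZ"], ax, "NZ"))
        groups.append(_Group("NH_donor", coords["NZ"], ax, "NZ"))
    if res == "ARG" and have("NE", "CZ", "NH1", "NH2"):
        cz = coords["CZ"]
        ax = unit((coords["NH1"] - cz) + (coords["NH2"] - cz))
        groups.append(_Group("arg_cation", cz, ax, "CZ"))
        for nh in ("NH1", "NH2"):
            groups.append(_Group("NH_donor", coords[nh], unit(coords[nh] - cz), nh))
    if res in AROMATIC_RING_ATOMS and have(*AROMATIC_RING_ATOMS[res]):
        center, normal = _ring_center_normal(coords, AROMATIC_RING_ATOMS[res])
        groups.append(_Group("aromatic_ring", center, normal, "ring"))
    if res == "HIS" and have(*HIS_RING_ATOMS):
        center, normal = _ring_center_normal(coords, HIS_RING_ATOMS)
        groups.append(_Group("his_ring", center, normal, "ring"))
        if have("CG", "ND1"):
            groups.append(_Group("NH_donor", coords["ND1"], unit(coords["ND1"] - coords["CG"]), "ND1"))
        if have("CE1", "NE2"):
            groups.append(_Group("NH_donor", coords["NE2"], unit(coords["NE2"] - coords["CE1"]), "NE2"))
    return groups


_GROUP_ROLE = {
    "NH_donor": "donor",
    "OH_donor": "donor",
    "carbonyl_O": "acceptor",
    "hydroxyl_O": "acceptor",
    "carboxylate_C": "anion",
    "lys_cation": "cation",
    "arg_cation": "cation",
    "aromatic_ring": "ring",
    "his_ring": "ring",
}

_PLANAR_FAMILIES = {"pipi_parallel", "pipi_tshaped", "hispi_parallel", "hispi_tshaped",
                    "cation_pi_arg", "cation_pi_lys"}


def _orthonormal_pair(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(unit(normal), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(normal, ref))
    v = unit(np.cross(normal, u))
    return u, v


def _emit_sites_for_group(
    group: _Group,
    specs: dict[str, InteractionSpec],
) -> list[InteractionSite]:
    sites: list[InteractionSite] = []
    for spec in specs.values():
        # anchor side
        if spec.anchor == group.kind:
            sites.append(
                InteractionSite(
                    position=group.position,
                    family=spec.family,
                    kind="anchor",
                    role=_GROUP_ROLE[group.kind],
                    direction=group.axis,
                    group_atom=group.label,
                )
            )
        # projection side
        if spec.projection_from == group.kind:
            if group.kind in ("aromatic_ring", "his_ring"):
                for sign in (1.0, -1.0):
                    n = sign * group.axis
                    base = group.position + spec.ideal_distance * n
                    if spec.horizontal_offset > 0:
                        u, v = _orthonormal_pair(group.axis)
                        offsets = [u, -u, v, -v]
                        for off in offsets:
                            sites.append(
                                InteractionSite(
                                    position=base + spec.horizontal_offset * off,
                                    family=spec.family,
                                    kind="projection",
                                    role="ring",
                                    direction=n,
                                    group_atom=group.label,
                                )
                            )
                    else:
                        sites.append(
                            InteractionSite(
                                position=base,
                                family=spec.family,
                                kind="projection",
                                role="ring",
                                direction=n,
                                group_atom=group.label,
                            )
                        )
            else:
                sites.append(
                    InteractionSite(
                        position=group.position + spec.ideal_distance * group.axis,
                        family=spec.family,
                        kind="projection",
                        role=_GROUP_ROLE[group.kind],
                        direction=group.axis,
                        group_atom=group.label,
                    )
                )
    return sites


def sites_for_residue(
    residue: Residue,
    prev_c: Optional[np.ndarray],
    rotamers: Optional[RotamerSet] = None,
    specs: Optional[dict[str, InteractionSpec]] = None,
    include_backbone: bool = True,
    source_loop: str = "",
) -> list[InteractionSite]:
    """All ideal-interaction sites of one residue: native + library rotamers.

    Rotamer index 0 is the native conformation as recorded; indices >= 1
    rebuild the side chain at library dihedrals.  Only the native residue
    type is used.
    """
    specs = specs or INTERACTION_SPECS
    key = f"{residue.chain_id}:{residue.seq_id}:{residue.res_name}"
    out: list[InteractionSite] = []

    def emit(coords: dict[str, np.ndarray], rot_idx: int, backbone: bool) -> None:
        for g in _residue_groups(residue, coords, prev_c, include_backbone=backbone):
            for s in _emit_sites_for_group(g, specs):
                s.residue_key = key
                s.rotamer_index = rot_idx
                s.source_loop = source_loop
                out.append(s)

    native = {a.name: a.coord for a in residue.atoms}
    emit(native, 0, include_backbone)

    if rotamers is not None and residue.res_name in ROTATABLE_RESIDUES:
        if residue.has_atom("N") and residue.has_atom("CA") and residue.has_atom("C"):
            for idx, (chis, _p) in enumerate(rotamers.for_residue(residue.res_name), start=1):
                rebuilt = place_sidechain(residue, chis)
                coords = {a.name: a.coord for a in residue.atoms if a.name in ("N", "CA", "C", "O")}
                coords.update({a.name: a.coord for a in rebuilt})
                emit(coords, idx, False)  # backbone groups already emitted once
    return out


def enumerate_sites(
    residues: Sequence[Residue],
    rotamers: Optional[RotamerSet] = None,
    specs: Optional[dict[str, InteractionSpec]] = None,
    include_backbone: bool = True,
    source_loop: str = "",
) -> list[InteractionSite]:
    """Sites for a contiguous stretch of residues (a loop or an epitope)."""
    out: list[InteractionSite] = []
    for i, res in enumerate(residues):
        prev_c = None
        if i > 0 and residues[i - 1].has_atom("C"):
            prev_c = residues[i - 1].atom("C").coord
        out.extend(
            sites_for_residue(
                res, prev_c, rotamers, specs,
                include_backbone=include_backbone, source_loop=source_loop,
            )
        )
    return out


def epitope_sites(
    target,
    epitope_residues: Sequence[Residue],
    specs: Optional[dict[str, InteractionSpec]] = None,
    rotamers: Optional[RotamerSet] = None,
    include_backbone: bool = True,
) -> list[InteractionSite]:
    """Ideal-interaction sites around the declared epitope of a target."""
    if not epitope_residues:
        raise ValueError("empty epitope")
    # previous residues looked up in the parent structure for amide H geometry
    out: list[InteractionSite] = []
    for res in epitope_residues:
        prev_c = None
        if target is not None and res.chain_id in getattr(target, "chains", {}):
            chain = target.chains[res.chain_id]
            idx = next(
                (i for i, r in enumerate(chain) if r.seq_id == res.seq_id and
                 r.insertion_code == res.insertion_code),
                None,
            )
            if idx is not None and idx > 0 and chain[idx - 1].has_atom("C"):
                prev_c = chain[idx - 1].atom("C").coord
        out.extend(
            sites_for_residue(res, prev_c, rotamers, specs, include_backbone=include_backbone)
        )
    return out


# ---------------------------------------------------------------------------
# Complementarity
# ---------------------------------------------------------------------------


def _secondary_ok(proj: InteractionSite, anchor: InteractionSite, cone_deg: float) -> bool:
    spec = INTERACTION_SPECS[proj.family]
    if spec.secondary == "head_on":
        # emitting axis anti-aligned with the anchor group's outward axis
        return angle_between(proj.direction, -anchor.direction) <= cone_deg
    if spec.secondary == "parallel_planes":
        a = angle_between(proj.direction, anchor.direction)
        return min(a, 180.0 - a) <= cone_deg
    if spec.secondary == "perpendicular_planes":
        a = angle_between(proj.direction, anchor.direction)
        return abs(a - 90.0) <= cone_deg
    raise ValueError(f"unknown secondary constraint {spec.secondary!r}")


def is_complementary(
    site_a: InteractionSite,
    site_b: InteractionSite,
    cone_deg: float = DEFAULT_SECONDARY_CONE,
) -> bool:
    """True iff the two sites can realize the same interaction family.

    Requires one projection and one anchor of the same family with the
    family's secondary angular constraint satisfied.  Position agreement is
    checked separately by the placement search.
    """
    if site_a.family != site_b.family:
        return False
    kinds = {site_a.kind, site_b.kind}
    if kinds != {"projection", "anchor"}:
        return False
    proj = site_a if site_a.kind == "projection" else site_b
    anchor = site_b if proj is site_a else site_a
    return _secondary_ok(proj, anchor, cone_deg)
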