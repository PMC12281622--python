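"""Protein structure container, PDB I/O, and atom typing.

Structures are parsed from PDB text via gemmi into a light in-memory model
(:class:`StructureModel`) holding chains of :class:`Residue` objects, each an
ordered list of :class:`Atom`.  All downstream geometry and energetics operate
on heavy atoms only; hydrogens are dropped at parse time and donor hydrogens
are inferred from heavy-atom geometry where needed.

Atom typing (van der Waals radii, template partial charges, formal-charge
class) is applied from packaged YAML tables; histidine is never classified as
charged (binding is assumed to occur at physiological pH).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np
import yaml

from .geometry import unit

WATER_NAMES = {"HOH", "WAT", "DOD"}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESIDUES = set(AA3_TO_1)


def _load_yaml(name: str) -> dict:
    with resources.files("petei.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


_VDW = _load_yaml("vdw_radii.yaml")
_CHG = _load_yaml("charges.yaml")

VDW_RADII: dict[str, float] = {k.upper(): float(v) for k, v in _VDW["radii"].items()}
VDW_DEFAULT: float = float(_VDW["default"])
PARTIAL_CHARGES: dict[str, dict[str, float]] = {
    res: {a: float(q) for a, q in atoms.items()}
    for res, atoms in _CHG["partial_charges"].items()
}
LJ_PARAMS: dict[str, dict[str, float]] = {
    k.upper(): {"epsilon": float(v["epsilon"]), "rmin_half": float(v["rmin_half"])}
    for k, v in _CHG["lennard_jones"].items()
    if k != "default"
}
LJ_DEFAULT = {
    "epsilon": float(_CHG["lennard_jones"]["default"]["epsilon"]),
    "rmin_half": float(_CHG["lennard_jones"]["default"]["rmin_half"]),
}


@dataclass(frozen=True)
class ChargeRules:
    """Which atoms count as formally charged for charge-clash detection.

    Defaults follow the convention used throughout: the side-chain nitrogens
    of Lys and Arg are positive, the carboxylate oxygens of Asp and Glu are
    negative, and histidine is never treated as charged.
    """

    positive_atoms: frozenset[tuple[str, str]] = frozenset(
        (res, atom)
        for res, atoms in _CHG["formal_charge_class"]["positive"].items()
        for atom in atoms
    )
    negative_atoms: frozenset[tuple[str, str]] = frozenset(
        (res, atom)
        for res, atoms in _CHG["formal_charge_class"]["negative"].items()
        for atom in atoms
    )
    histidine_charged: bool = False

    def __post_init__(self) -> None:
        if self.histidine_charged:
            raise ValueError("histidine must not be treated as charged")
        for res, _ in self.positive_atoms | self.negative_atoms:
            if res == "HIS":
                raise ValueError("histidine atoms cannot be in the charge rules")

    def classify(self, res_name: str, atom_name: str) -> str:
        if (res_name, atom_name) in self.positive_atoms:
            return "positive"
        if (res_name, atom_name) in self.negative_atoms:
            return "negative"
        return "neutral"


DEFAULT_CHARGE_RULES = ChargeRules()


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    vdw_radius: float
    partial_charge: float = 0.0
    formal_charge_class: str = "neutral"
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


@dataclass
class Residue:
    res_name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    chain_id: str = ""

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.res_name} {self.seq_id}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.atom(n).coord for n in names])

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.res_name, "X")

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_RESIDUES

    def has_backbone(self) -> bool:
        return all(self.has_atom(n) for n in ("N", "CA", "C", "O"))

    def copy(self) -> "Residue":
        return Residue(
            res_name=self.res_name,
            seq_id=self.seq_id,
            atoms=[a.copy() for a in self.atoms],
            insertion_code=self.insertion_code,
            chain_id=self.chain_id,
        )

    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)


@dataclass
class StructureModel:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [r.key() for r in residues]
            if keys != sorted(keys):
                raise ValueError(f"chain {cid}: residues not in (seq_id, icode) order")

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms() if a.is_heavy]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms()]
        return np.array(pts) if pts else np.zeros((0, 3))

    def residue(self, chain_id: str, seq_id: int, icode: str = "") -> Residue:
        for r in self.chains[chain_id]:
            if r.seq_id == seq_id and r.insertion_code == icode:
                return r
        raise KeyError(f"residue {chain_id}:{seq_id}{icode} not found in {self.id}")

    def select_range(self, chain_id: str, start: int, end: int) -> list[Residue]:
        """Residues with start <= seq_id <= end (author numbering, inclusive)."""
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not found in {self.id}")
        return [r for r in self.chains[chain_id] if start <= r.seq_id <= end]

    def transform(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (x -> x @ R.T + t)."""
        m = self.copy()
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        for a in m.atoms():
            a.coord = a.coord @ R.T + t
        return m

    def translate(self, t: np.ndarray) -> "StructureModel":
        return self.transform(np.eye(3), t)

    def copy(self) -> "StructureModel":
        return StructureModel(
            id=self.id,
            chains={cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            provenance=self.provenance,
        )


class PDBParseError(ValueError):
    pass


def _make_atom(name: str, element: str, pos: np.ndarray, res_name: str,
               occupancy: float = 1.0,
               charge_rules: ChargeRules = DEFAULT_CHARGE_RULES) -> Atom:
    element = element.upper() or "C"
    return Atom(
        name=name,
        element=element,
        coord=pos,
        vdw_radius=VDW_RADII.get(element, VDW_DEFAULT),
        partial_charge=PARTIAL_CHARGES.get(res_name, {}).get(name, 0.0),
        formal_charge_class=charge_rules.classify(res_name, name),
        occupancy=occupancy,
    )


def make_atom(name: str, element: str, pos, res_name: str = "UNK") -> Atom:
    """Construct a typed atom at a position (radii/charges from the tables)."""
    return _make_atom(name, element, np.asarray(pos, dtype=float), res_name)


def _validate_pdb_lines(pdb_text: str) -> None:
    n_coord = 0
    for i, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_coord += 1
            if len(line) < 54:
                raise PDBParseError(f"line {i}: truncated ATOM/HETATM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {i}: unparseable coordinates") from exc
    if n_coord == 0:
        raise PDBParseError("no ATOM/HETATM records found")


def read_structure(
    pdb_text: str,
    chain_selection: Optional[set[str]] = None,
    structure_id: Optional[str] = None,
    keep_hetatm: bool = False,
    charge_rules: ChargeRules = DEFAULT_CHARGE_RULES,
) -> StructureModel:
    """Parse PDB-format text into a StructureModel.

    Only the first model of multi-model (e.g. NMR) entries is read.  Alternate
    locations are resolved to the highest-occupancy copy (ties: first
    encountered).  Waters are always dropped; other non-polymer HETATM
    residues are dropped unless ``keep_hetatm``.  Hydrogens are discarded.
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("structure contains no models")
    model = st[0]

    available = {ch.name for ch in model}
    if chain_selection is not None:
        if not chain_selection:
            raise ValueError("empty chain selection")
        missing = set(chain_selection) - available
        if missing:
            raise KeyError(f"chain not found: {sorted(missing)}")

    chains: dict[str, list[Residue]] = {}
    for ch in model:
        if chain_selection is not None and ch.name not in chain_selection:
            continue
        residues: list[Residue] = []
        for res in ch:
            if res.name in WATER_NAMES:
                continue
            if res.het_flag == "H" and res.name not in STANDARD_RESIDUES and not keep_hetatm:
                continue
            # alt-loc resolution: highest occupancy, tie -> first encountered
            chosen: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.name == "H" or at.element.name == "D":
                    continue
                prev = chosen.get(at.name)
                if prev is None or at.occ > prev.occ + 1e-9:
                    chosen[at.name] = at
            if not chosen:
                continue
            atoms = [
                _make_atom(
                    at.name,
                    at.element.name,
                    np.array([at.pos.x, at.pos.y, at.pos.z]),
                    res.name,
                    occupancy=at.occ,
                    charge_rules=charge_rules,
                )
                for at in chosen.values()
            ]
            residues.append(
                Residue(
                    res_name=res.name,
                    seq_id=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip(),
                    atoms=atoms,
                    chain_id=ch.name,
                )
            )
        if residues:
            residues.sort(key=lambda r: r.key())
            chains[ch.name] = residues

    if not chains:
        raise PDBParseError("no residues retained after filtering")
    return StructureModel(
        id=structure_id or st.name or "structure",
        chains=chains,
        provenance=f"parsed from PDB text; chains={sorted(chains)}",
    )


def write_structure(model: StructureModel) -> str:
    """Serialize a StructureModel as PDB-format text (ATOM/TER/END records)."""
    st = gemmi.Structure()
    st.name = model.id[:4] if model.id else "XXXX"
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gch = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.het_flag = "A" if res.is_standard else "H"
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            for a in res.atoms:
                if np.any(np.abs(a.coord) >= 10000.0) or np.any(a.coord <= -1000.0):
                    raise ValueError(
                        f"coordinate out of PDB fixed-width range for atom {a.name}"
                    )
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.coord)
                gat.occ = a.occupancy
                gat.b_iso = 0.0
                gres.add_atom(gat)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.minimal_file = True
    opts.ter_records = True
    return st.make_pdb_string(opts)


def virtual_cbeta(residue: Residue) -> np.ndarray:
    """CB coordinate; for glycine an ideal CB built from N/CA/C.

    The constructed point sits 1.53 Å from CA along the ideal tetrahedral
    direction, and commutes with rigid transforms of the backbone.
    """
    if residue.has_atom("CB"):
        return residue.atom("CB").coord.copy()
    for name in ("N", "CA", "C"):
        if not residue.has_atom(name):
            raise KeyError(
                f"residue {residue.res_name} {residue.seq_id}: missing backbone atom {name}"
            )
    n = residue.atom("N").coord
    ca = residue.atom("CA").coord
    c = residue.atom("C").coord
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    direction = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return ca + 1.53 * unit(direction)


def concatenate(models: Iterable[StructureModel], new_id: str = "complex") -> StructureModel:
    """Merge models into one; clashing chain ids are suffixed."""
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    chains: dict[str, list[Residue]] = {}
    for m in models:
        for cid, residues in m.chains.items():
            out_cid = cid
            if out_cid in chains:
                out_cid = next(c for c in alphabet if c not in chains)
            chains[out_cid] = [r.copy() for r in residues]
    return StructureModel(id=new_id, chains=chains)
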