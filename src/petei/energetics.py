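"""Pairwise energies, clash counting, SASA, and binding-score computation.

The interaction energy is a simplified Coulomb + Lennard-Jones sum over
cross-group heavy-atom pairs within a cutoff, with template partial charges
and element-based LJ parameters (Lorentz-Berthelot combining).  It is a
deliberately lightweight stand-in for a full force field: the same screening
thresholds are applied to it, but absolute values are not comparable to
CHARMM or Rosetta output.

Two steric-clash definitions coexist:

* ``database`` mode - two heavy atoms closer than the full sum of their van
  der Waals radii (used when screening harvested loops);
* ``design`` mode - closer than 80% of that sum (used when screening
  designed complexes).

A charge-charge clash is two like-charged atoms (Lys/Arg side-chain N,
Asp/Glu carboxylate O) within 4.2 Å.

SASA is Shrake-Rupley with a deterministic Fibonacci sphere lattice
(960 points/atom by default); buried surface area of a complex is
SASA(A) + SASA(B) - SASA(AB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import (
    Atom,
    ChargeRules,
    DEFAULT_CHARGE_RULES,
    LJ_DEFAULT,
    LJ_PARAMS,
    StructureModel,
    concatenate,
)

COULOMB_CONSTANT = 332.0636  # kcal*Å/(mol*e^2)
CHARGE_CLASH_DISTANCE = 4.2  # Å


@dataclass
class EnergyParams:
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric: float = 4.0
    cutoff: float = 12.0
    lj_enabled: bool = True

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class ClashMode:
    mode: str

    @property
    def threshold_fraction(self) -> float:
        return {"database": 1.0, "design": 0.8}[self.mode]


DATABASE_CLASH = ClashMode("database")
DESIGN_CLASH = ClashMode("design")


@dataclass
class ComplexScore:
    binding_energy: float
    buried_surface_area: float
    be_bsa: Optional[float]
    warnings: list[str] = field(default_factory=list)


def _as_atoms(group: Iterable[Atom] | StructureModel) -> list[Atom]:
    if isinstance(group, StructureModel):
        return list(group.atoms())
    return list(group)


def _check_disjoint(a: Sequence[Atom], b: Sequence[Atom]) -> None:
    ids_a = {id(x) for x in a}
    if any(id(x) in ids_a for x in b):
        raise ValueError("atom groups must be disjoint")


def pair_energy(
    group_a: Iterable[Atom] | StructureModel,
    group_b: Iterable[Atom] | StructureModel,
    params: Optional[EnergyParams] = None,
) -> float:
    """Coulomb + LJ interaction energy (kcal/mol) between two atom groups."""
    params = params or EnergyParams()
    a = _as_atoms(group_a)
    b = _as_atoms(group_b)
    _check_disjoint(a, b)
    if not a or not b:
        return 0.0

    xa = np.array([at.coord for at in a])
    xb = np.array([at.coord for at in b])
    qa = np.array([at.partial_charge for at in a])
    qb = np.array([at.partial_charge for at in b])

    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    within = d <= params.cutoff
    d_safe = np.where(d < 1e-6, 1e-6, d)

    # contributions are sorted before summation so the result is exactly
    # symmetric in the two arguments (same multiset, same summation order)
    energy = 0.0
    qq = np.outer(qa, qb)
    if np.any(qq != 0):
        coul = params.coulomb_constant * qq / (params.dielectric * d_safe)
        energy += float(np.sum(np.sort(coul[within], axis=None)))

    if params.lj_enabled:
        def lj(at: Atom) -> tuple[float, float]:
            p = LJ_PARAMS.get(at.element, LJ_DEFAULT)
            return p["epsilon"], p["rmin_half"]

        eps_a, rm_a = map(np.array, zip(*[lj(at) for at in a]))
        eps_b, rm_b = map(np.array, zip(*[lj(at) for at in b]))
        eps = np.sqrt(np.outer(eps_a, eps_b))
        rmin = rm_a[:, None] + rm_b[None, :]
        frac6 = (rmin / d_safe) ** 6
        ljm = eps * (frac6 * frac6 - 2.0 * frac6)
        energy += float(np.sum(np.sort(ljm[within], axis=None)))
    return energy


def count_clashes(
    group_a: Iterable[Atom] | StructureModel,
    group_b: Iterable[Atom] | StructureModel,
    mode: ClashMode = DATABASE_CLASH,
) -> int:
    """Cross-group heavy-atom pairs strictly closer than the vdW threshold."""
    a = [at for at in _as_atoms(group_a) if at.is_heavy]
    b = [at for at in _as_atoms(group_b) if at.is_heavy]
    if not a or not b:
        return 0
    xa = np.array([at.coord for at in a])
    xb = np.array([at.coord for at in b])
    ra = np.array([at.vdw_radius for at in a])
    rb = np.array([at.vdw_radius for at in b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    thresh = mode.threshold_fraction * (ra[:, None] + rb[None, :])
    return int(np.sum(d < thresh))


def count_charge_clashes(
    group_a: Iterable[Atom] | StructureModel,
    group_b: Iterable[Atom] | StructureModel,
    rules: ChargeRules = DEFAULT_CHARGE_RULES,
    distance: float = CHARGE_CLASH_DISTANCE,
) -> int:
    """Cross-group pairs of like-charged atoms strictly within ``distance`` Å."""
    a = [at for at in _as_atoms(group_a) if at.formal_charge_class != "neutral"]
    b = [at for at in _as_atoms(group_b) if at.formal_charge_class != "neutral"]
    if not a or not b:
        return 0
    xa = np.array([at.coord for at in a])
    xb = np.array([at.coord for at in b])
    same = np.array(
        [[at_a.formal_charge_class == at_b.formal_charge_class for at_b in b] for at_a in a]
    )
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return int(np.sum(same & (d < distance)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    model: StructureModel | Iterable[Atom],
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Shrake-Rupley solvent-accessible surface area (Å²), heavy atoms only."""
    atoms = [a for a in _as_atoms(model) if a.is_heavy]
    if not atoms:
        raise ValueError("cannot compute SASA of an empty model")
    # coincident identical spheres describe one surface; keep a single copy
    seen: set[tuple] = set()
    unique: list = []
    for a in atoms:
        key = (round(a.vdw_radius, 6), *(round(float(x), 6) for x in a.coord))
        if key not in seen:
            seen.add(key)
            unique.append(a)
    atoms = unique
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = float(radii.max())
    total = 0.0
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * sphere
        neighbors = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :], axis=2)
            exposed = np.all(d >= radii[neighbors][None, :], axis=1)
            n_exposed = int(np.sum(exposed))
        else:
            n_exposed = n_points
        total += 4.0 * np.pi * r * r * n_exposed / n_points
    return float(total)


def buried_surface_area(
    binder: StructureModel, target: StructureModel, probe: float = 1.4, n_points: int = 960
) -> float:
    complex_model = concatenate([binder, target])
    return (
        sasa(binder, probe, n_points)
        + sasa(target, probe, n_points)
        - sasa(complex_model, probe, n_points)
    )


def score_complex(
    binder: StructureModel,
    target: StructureModel,
    params: Optional[EnergyParams] = None,
    probe: float = 1.4,
    n_points: int = 960,
    bsa_floor: float = 1.0,
) -> ComplexScore:
    """Binding energy, buried surface area, and their ratio (BE/BSA).

    ``be_bsa`` is None (flagged undefined) when the interface buries less
    than ``bsa_floor`` Å².  Deep inter-model overlaps (< 50% of the vdW sum)
    are recorded as warnings but do not abort scoring.
    """
    params = params or EnergyParams()
    warnings: list[str] = []
    overlap = count_clashes(binder, target, ClashMode("design"))
    if overlap:
        # re-check at the tighter 50% rule for the warning
        deep = _count_fraction_clashes(binder, target, 0.5)
        if deep:
            warnings.append(f"{deep} heavy-atom pair(s) overlap below 50% of vdW sum")
    be = pair_energy(binder, target, params)
    bsa = buried_surface_area(binder, target, probe, n_points)
    bsa = max(bsa, 0.0)
    be_bsa = be / bsa if bsa >= bsa_floor else None
    if be_bsa is None:
        warnings.append("buried surface area ~ 0; BE/BSA undefined")
    return ComplexScore(binding_energy=be, buried_surface_area=bsa, be_bsa=be_bsa, warnings=warnings)


def _count_fraction_clashes(a, b, fraction: float) -> int:
    atoms_a = [at for at in _as_atoms(a) if at.is_heavy]
    atoms_b = [at for at in _as_atoms(b) if at.is_heavy]
    if not atoms_a or not atoms_b:
        return 0
    xa = np.array([at.coord for at in atoms_a])
    xb = np.array([at.coord for at in atoms_b])
    ra = np.array([at.vdw_radius for at in atoms_a])
    rb = np.array([at.vdw_radius for at in atoms_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return int(np.sum(d < fraction * (ra[:, None] + rb[None, :])))
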