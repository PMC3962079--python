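"""Structure input/output and per-atom solvent bookkeeping.

Reads PDB files into a light-weight atom list carrying everything the
scattering engines need: element, coordinates, van der Waals radius, the
solvent volume the atom displaces, the number of implicit hydrogens folded
into the heavy atom, and the fraction of its surface accessible to solvent.

Crystal structures usually lack hydrogen positions, so by default each
heavy atom absorbs its bonded hydrogens ("implicit-hydrogen mode"): the
hydrogen electrons are added to the heavy atom's form factor instead of
being modelled as separate scatterers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

import gemmi

__all__ = [
    "Atom",
    "Structure",
    "DEFAULT_VDW_RADII",
    "read_pdb",
    "write_pdb",
    "assign_volumes",
    "assign_implicit_hydrogens",
    "compute_sasa",
    "d_max",
]

#: Bondi-style van der Waals radii in Angstrom, overridable per call.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "NA": 2.27,
    "MG": 1.73,
    "CL": 1.75,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.04,
    "ZN": 1.39,
}

# Hydrogens bonded to each side-chain heavy atom of the standard residues.
# Keyed (residue name, atom name); backbone atoms are handled generically.
_SIDECHAIN_H: dict[tuple[str, str], int] = {
    ("ALA", "CB"): 3,
    ("ARG", "CB"): 2, ("ARG", "CG"): 2, ("ARG", "CD"): 2, ("ARG", "NE"): 1,
    ("ARG", "CZ"): 0, ("ARG", "NH1"): 2, ("ARG", "NH2"): 2,
    ("ASN", "CB"): 2, ("ASN", "CG"): 0, ("ASN", "OD1"): 0, ("ASN", "ND2"): 2,
    ("ASP", "CB"): 2, ("ASP", "CG"): 0, ("ASP", "OD1"): 0, ("ASP", "OD2"): 0,
    ("CYS", "CB"): 2, ("CYS", "SG"): 1,
    ("GLN", "CB"): 2, ("GLN", "CG"): 2, ("GLN", "CD"): 0, ("GLN", "OE1"): 0,
    ("GLN", "NE2"): 2,
    ("GLU", "CB"): 2, ("GLU", "CG"): 2, ("GLU", "CD"): 0, ("GLU", "OE1"): 0,
    ("GLU", "OE2"): 0,
    ("HIS", "CB"): 2, ("HIS", "CG"): 0, ("HIS", "ND1"): 1, ("HIS", "CD2"): 1,
    ("HIS", "CE1"): 1, ("HIS", "NE2"): 0,
    ("ILE", "CB"): 1, ("ILE", "CG1"): 2, ("ILE", "CG2"): 3, ("ILE", "CD1"): 3,
    ("LEU", "CB"): 2, ("LEU", "CG"): 1, ("LEU", "CD1"): 3, ("LEU", "CD2"): 3,
    ("LYS", "CB"): 2, ("LYS", "CG"): 2, ("LYS", "CD"): 2, ("LYS", "CE"): 2,
    ("LYS", "NZ"): 3,
    ("MET", "CB"): 2, ("MET", "CG"): 2, ("MET", "SD"): 0, ("MET", "CE"): 3,
    ("PHE", "CB"): 2, ("PHE", "CG"): 0, ("PHE", "CD1"): 1, ("PHE", "CD2"): 1,
    ("PHE", "CE1"): 1, ("PHE", "CE2"): 1, ("PHE", "CZ"): 1,
    ("PRO", "CB"): 2, ("PRO", "CG"): 2, ("PRO", "CD"): 2,
    ("SER", "CB"): 2, ("SER", "OG"): 1,
    ("THR", "CB"): 1, ("THR", "OG1"): 1, ("THR", "CG2"): 3,
    ("TRP", "CB"): 2, ("TRP", "CG"): 0, ("TRP", "CD1"): 1, ("TRP", "CD2"): 0,
    ("TRP", "NE1"): 1, ("TRP", "CE2"): 0, ("TRP", "CE3"): 1,
    ("TRP", "CZ2"): 1, ("TRP", "CZ3"): 1, ("TRP", "CH2"): 1,
    ("TYR", "CB"): 2, ("TYR", "CG"): 0, ("TYR", "CD1"): 1, ("TYR", "CD2"): 1,
    ("TYR", "CE1"): 1, ("TYR", "CE2"): 1, ("TYR", "CZ"): 0, ("TYR", "OH"): 1,
    ("VAL", "CB"): 1, ("VAL", "CG1"): 3, ("VAL", "CG2"): 3,
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Atom:
    """One scatterer: a heavy atom (plus its implicit hydrogens) or a water.

    ``displaced_volume`` is the solvent volume the atom excludes, in cubic
    Angstrom; ``sasa_fraction`` is the fraction of its solvent-accessible
    sphere that is exposed, in [0, 1], used to weight the hydration-shell
    form-factor term.
    """

    element: str
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float = 0.0
    displaced_volume: float = 0.0
    n_implicit_h: int = 0
    sasa_fraction: float = 0.0
    sasa_area: float = 0.0  # absolute exposed area, A^2
    is_calpha: bool = False
    is_water: bool = False
    name: str = ""
    res_name: str = ""
    res_seq: int = 1
    chain: str = "A"

    def __post_init__(self) -> None:
        self.element = self.element.upper()
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("Atom position must be a 3-vector")
        if not self.name:
            self.name = self.element


@dataclass
class Structure:
    """Ordered collection of atoms with an identifier."""

    atoms: list[Atom] = field(default_factory=list)
    identifier: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def positions(self) -> np.ndarray:
        """All coordinates as an (N, 3) array."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.position for a in self.atoms])

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def calpha_positions(self) -> np.ndarray:
        pos = [a.position for a in self.atoms if a.is_calpha]
        if not pos:
            return np.zeros((0, 3))
        return np.vstack(pos)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Rigidly transformed copy (rotation applied first)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        new_atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return Structure(atoms=new_atoms, identifier=self.identifier)


class PDBParseError(ValueError):
    """Raised when a PDB file yields no usable atoms or a bad record."""


def _element_from_gemmi(atom: gemmi.Atom, res_name: str) -> str:
    el = atom.element.name.upper().strip()
    if el and el != "X":
        return el
    # fallback: first alphabetic character of the atom name that is not a digit
    name = atom.name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise PDBParseError(
        f"cannot resolve element for atom '{atom.name}' in residue {res_name}"
    )


def _implicit_h_count(res_name: str, atom_name: str, element: str) -> int:
    if element == "H":
        return 0
    if res_name in _WATER_RESNAMES:
        return 2 if element == "O" else 0
    key = (res_name, atom_name)
    if key in _SIDECHAIN_H:
        return _SIDECHAIN_H[key]
    if res_name in _AMINO_ACIDS or atom_name in ("N", "CA", "C", "O", "OXT"):
        if atom_name == "N":
            return 0 if res_name == "PRO" else 1
        if atom_name == "CA":
            return 2 if res_name == "GLY" else 1
        if atom_name in ("C", "O"):
            return 0
        if atom_name == "OXT":
            return 1
    return 0


def assign_implicit_hydrogens(structure: Structure) -> Structure:
    """Set ``n_implicit_h`` on every atom from standard per-atom-name counts."""
    for a in structure.atoms:
        a.n_implicit_h = _implicit_h_count(a.res_name, a.name, a.element)
    return structure


def read_pdb(path: str | Path, *, hydrogen_mode: str = "implicit",
             keep_waters: bool = True,
             radii: Mapping[str, float] | None = None) -> Structure:
    """Read the first model of a PDB file.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM/HETATM record.
    hydrogen_mode:
        ``"implicit"`` (default) drops explicit hydrogen records and folds
        standard hydrogen counts into each heavy atom; ``"explicit"`` keeps
        hydrogen atoms as scatterers with no implicit count.
    keep_waters:
        Include HETATM waters (flagged ``is_water``).
    radii:
        Van der Waals radius table; defaults to :data:`DEFAULT_VDW_RADII`.
        Atoms whose element is absent get radius/volume 0 and must be fixed
        with :func:`assign_volumes` before scattering.

    For alternate locations only the conformer with the highest occupancy is
    kept (ties broken toward the first encountered). Only the first MODEL of
    multi-model files is read.
    """
    if hydrogen_mode not in ("implicit", "explicit"):
        raise ValueError(f"unknown hydrogen_mode {hydrogen_mode!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models")
    model = st[0]
    radii = DEFAULT_VDW_RADII if radii is None else dict(radii)

    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            is_water = res.name in _WATER_RESNAMES
            if is_water and not keep_waters:
                continue
            # altloc resolution: best occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for ga in res:
                if ga.name not in best:
                    best[ga.name] = ga
                    order.append(ga.name)
                elif ga.occ > best[ga.name].occ:
                    best[ga.name] = ga
            for name in order:
                ga = best[name]
                el = _element_from_gemmi(ga, res.name)
                if el == "H" and hydrogen_mode == "implicit":
                    continue
                n_h = (_implicit_h_count(res.name, name, el)
                       if hydrogen_mode == "implicit" else 0)
                r = radii.get(el, 0.0)
                atoms.append(Atom(
                    element=el,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    vdw_radius=r,
                    displaced_volume=(4.0 / 3.0) * math.pi * r ** 3,
                    n_implicit_h=n_h,
                    is_calpha=(name == "CA" and el == "C"),
                    is_water=is_water,
                    name=name,
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    chain=chain.name,
                ))
    if not atoms:
        raise PDBParseError(f"{path}: no parsable ATOM/HETATM records")
    return Structure(atoms=atoms, identifier=path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB (ATOM/HETATM, element in columns 77-78)."""
    path = Path(path)
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.is_water else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        res_name = a.res_name or ("HOH" if a.is_water else "UNK")
        x, y, z = a.position
        lines.append(
            f"{record}{i % 100000:5d} {name:<4.4s} {res_name:<3.3s} "
            f"{a.chain[:1]}{a.res_seq % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2.2s}  "
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def assign_volumes(structure: Structure,
                   radii: Mapping[str, float] | None = None) -> Structure:
    """Set each atom's displaced solvent volume to (4/3) pi r_vdw^3.

    The dummy-atom excluded-solvent model treats each atom as displacing a
    sphere of its van der Waals radius.
    """
    radii = DEFAULT_VDW_RADII if radii is None else dict(radii)
    missing = sorted({a.element for a in structure.atoms if a.element not in radii})
    if missing:
        raise KeyError(
            f"no van der Waals radius for element(s): {', '.join(missing)}"
        )
    for a in structure.atoms:
        r = radii[a.element]
        if r < 0:
            raise ValueError(f"negative radius for {a.element}")
        a.vdw_radius = r
        a.displaced_volume = (4.0 / 3.0) * math.pi * r ** 3
    return structure


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere.

    Golden-spiral points on one hemisphere plus their antipodes: the set
    is exactly centrosymmetric, so mirror-image environments (e.g. two
    identical touching atoms) get identical exposed counts. ``n`` is
    rounded up to even.
    """
    half = (n + 1) // 2
    k = np.arange(half, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - k / half  # upper hemisphere only
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    upper = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return np.vstack([upper, -upper])


def compute_sasa(structure: Structure, probe_radius: float = 1.4,
                 n_sphere_points: int = 960) -> Structure:
    """Shrake-Rupley solvent-accessible surface area per atom.

    Each atom is given a test sphere of radius r_vdw + probe sampled at
    ``n_sphere_points`` quasi-uniform points; a point is exposed if it lies
    outside every neighbour's accessible sphere. ``sasa_fraction`` is the
    exposed fraction and ``sasa_area`` the corresponding absolute area.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_sphere_points < 16:
        raise ValueError("n_sphere_points must be >= 16")
    n = len(structure.atoms)
    if n == 0:
        return structure
    pos = structure.positions()
    radii = np.array([a.vdw_radius for a in structure.atoms])
    if np.any(radii <= 0):
        raise ValueError("all atoms need a positive vdW radius; "
                         "run assign_volumes first")
    acc = radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    n_pts = unit.shape[0]
    tree = cKDTree(pos)
    max_acc = acc.max()
    for i, atom in enumerate(structure.atoms):
        pts = pos[i] + acc[i] * unit
        neighbours = tree.query_ball_point(pos[i], acc[i] + max_acc)
        exposed = np.ones(n_pts, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            exposed &= d2 > acc[j] ** 2
        frac = float(exposed.sum()) / n_pts
        atom.sasa_fraction = frac
        atom.sasa_area = frac * 4.0 * math.pi * acc[i] ** 2
    return structure


def d_max(structure: Structure) -> float:
    """Largest interatomic distance in the structure, in Angstrom."""
    if len(structure.atoms) < 2:
        raise ValueError("d_max requires at least 2 atoms")
    return float(pdist(structure.positions()).max())
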