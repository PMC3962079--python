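"""Atomic form factors and the physical constants behind them.

The in-vacuo scattering factor of an atom is the Fourier transform of its
electron density, parameterised analytically as four Gaussians plus a
constant (Cromer-Mann form):

    f_v(q) = sum_k a_k * exp(-b_k * (q / 4 pi)^2) + c

with f_v(0) = Z, the electron count. The solvent displaced by the atom is
modelled as a Gaussian sphere of the atom's van der Waals volume
(dummy-atom model), and the hydration shell as a SASA-weighted water
contribution, giving the combined per-atom factor

    F(q) = f_v(q) - c1 * f_s(q) + c2 * S_i * f_w(q)

where c1 scales the excluded-volume contrast and c2 the shell density.

The 4-Gaussian parameterisation is accurate over the SAXS range
(q <~ 0.33 1/A); a guard warns beyond it and refuses service above
6 1/A unless explicitly overridden.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from saxskit.structure_io import Atom, Structure

__all__ = [
    "CromerMannCoefficients",
    "SolventModel",
    "FormFactorTable",
    "CROMER_MANN",
    "vacuum_ff",
    "excluded_ff",
    "water_ff",
    "combined_ff",
    "thomson_length",
    "amplitude_ratio",
    "water_electron_density",
    "q_from_angle",
    "load_coefficients_csv",
    "CM_VALID_Q",
    "CM_HARD_LIMIT_Q",
    "WATER_RHO0",
]

#: Upper edge of the well-validated 4-Gaussian range, 1/A.
CM_VALID_Q = 0.33
#: Beyond this the 4-Gaussian fit is unusable; a 6-Gaussian fit would be needed.
CM_HARD_LIMIT_Q = 6.0
#: Electron density of pure water, e/A^3.
WATER_RHO0 = 0.334

# -- physical constants (SI) used for the Thomson length -------------------
ELECTRON_CHARGE = 1.602e-19     # C
ELECTRON_MASS = 9.107e-31       # kg
SPEED_OF_LIGHT = 2.998e8        # m/s
VACUUM_PERMITTIVITY = 8.854e-12  # C^2 / (N m^2)

# CODATA 2018 values, selectable for users who prefer them.
_CODATA = {
    "q_e": 1.602176634e-19,
    "m_e": 9.1093837015e-31,
    "c": 2.99792458e8,
    "eps0": 8.8541878128e-12,
}

AVOGADRO = 6.02e23              # 1/mol
WATER_MOLAR_MASS = 18.0         # g/mol
WATER_ELECTRONS = 10            # electrons per molecule


@dataclass(frozen=True)
class CromerMannCoefficients:
    """4-Gaussian + constant parameterisation of one element's f_v(q)."""

    element: str
    z: int
    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: float

    def __post_init__(self) -> None:
        if any(ai < 0 for ai in self.a) or any(bi < 0 for bi in self.b):
            raise ValueError(f"{self.element}: negative Cromer-Mann coefficient")
        total = sum(self.a) + self.c
        if abs(total - self.z) >= 0.1:
            raise ValueError(
                f"{self.element}: f(0) = {total:.4f} does not match Z = {self.z}"
            )

    def evaluate(self, q: np.ndarray | float) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        s2 = (q / (4.0 * math.pi)) ** 2
        out = np.full_like(q, self.c, dtype=float)
        for ak, bk in zip(self.a, self.b):
            out += ak * np.exp(-bk * s2)
        return out if out.ndim else float(out)


# International-Tables 4-Gaussian coefficients for the elements found in
# proteins plus common counter-ions/cofactors (neutral species).
CROMER_MANN: dict[str, CromerMannCoefficients] = {
    cm.element: cm for cm in [
        CromerMannCoefficients("H", 1,
            (0.489918, 0.262003, 0.196767, 0.049879),
            (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
        CromerMannCoefficients("C", 6,
            (2.31000, 1.02000, 1.58860, 0.865000),
            (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
        CromerMannCoefficients("N", 7,
            (12.2126, 3.13220, 2.01250, 1.16630),
            (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
        CromerMannCoefficients("O", 8,
            (3.04850, 2.28680, 1.54630, 0.867000),
            (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
        CromerMannCoefficients("NA", 11,
            (4.76260, 3.17360, 1.26740, 1.11280),
            (3.28500, 8.84220, 0.313600, 129.424), 0.676000),
        CromerMannCoefficients("MG", 12,
            (5.42040, 2.17350, 1.22690, 2.30730),
            (2.82750, 79.2611, 0.380800, 7.19370), 0.858400),
        CromerMannCoefficients("P", 15,
            (6.43450, 4.17910, 1.78000, 1.49080),
            (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
        CromerMannCoefficients("S", 16,
            (6.90530, 5.20340, 1.43790, 1.58630),
            (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
        CromerMannCoefficients("CL", 17,
            (11.4604, 7.19640, 6.25560, 1.64550),
            (0.010400, 1.16620, 18.5194, 47.7784), -9.5574),
        CromerMannCoefficients("K", 19,
            (8.21860, 7.43980, 1.05190, 0.865900),
            (12.7949, 0.774800, 213.187, 41.6841), 1.42280),
        CromerMannCoefficients("CA", 20,
            (8.62660, 7.38730, 1.58990, 1.02110),
            (10.4421, 0.659900, 85.7484, 178.437), 1.37510),
        CromerMannCoefficients("MN", 25,
            (11.2819, 7.35730, 3.01930, 2.24410),
            (5.34090, 0.343200, 17.8674, 83.7543), 1.08960),
        CromerMannCoefficients("FE", 26,
            (11.7695, 7.35730, 3.52250, 2.30450),
            (4.76110, 0.307200, 15.3535, 76.8805), 1.03690),
        CromerMannCoefficients("ZN", 30,
            (14.0743, 7.03180, 5.16520, 2.41000),
            (3.26550, 0.233300, 10.3163, 58.7097), 1.30410),
    ]
}


def load_coefficients_csv(path: str | Path) -> dict[str, CromerMannCoefficients]:
    """Read coefficient overrides: element,Z,a1..a4,b1..b4,c per line."""
    table: dict[str, CromerMannCoefficients] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("element"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 11:
            raise ValueError(f"expected 11 fields, got {len(parts)}: {line!r}")
        el = parts[0].upper()
        z = int(parts[1])
        vals = [float(p) for p in parts[2:]]
        table[el] = CromerMannCoefficients(
            el, z, tuple(vals[0:4]), tuple(vals[4:8]), vals[8])
    return table


@dataclass
class SolventModel:
    """Bulk-solvent density and the two adjustable hydration parameters.

    rho0 is the electron density of the bulk solvent (0.334 e/A^3 for pure
    water); c1 scales the excluded-volume contrast and c2 the weight of the
    SASA-proportional hydration-shell term.
    """

    rho0: float = WATER_RHO0
    c1: float = 1.0
    c2: float = 0.0

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if self.c2 < 0:
            raise ValueError("c2 must be >= 0")


def _check_q_range(q: np.ndarray, allow_wide: bool) -> None:
    qmax = float(np.max(q)) if np.size(q) else 0.0
    if qmax > CM_HARD_LIMIT_Q and not allow_wide:
        raise ValueError(
            f"q = {qmax:.3g} 1/A exceeds the 4-Gaussian validity limit "
            f"({CM_HARD_LIMIT_Q} 1/A); pass allow_wide_q=True to override"
        )
    if qmax > CM_VALID_Q:
        warnings.warn(
            f"q up to {qmax:.3g} 1/A exceeds the well-validated 4-Gaussian "
            f"range (<= {CM_VALID_Q} 1/A)", stacklevel=3)


def vacuum_ff(element: str, n_h: int, q: np.ndarray | float, *,
              coefficients: Mapping[str, CromerMannCoefficients] | None = None,
              allow_wide_q: bool = False) -> np.ndarray | float:
    """In-vacuo form factor of an element with ``n_h`` implicit hydrogens.

    At q = 0 this equals Z + n_h, the total electron count of the heavy
    atom plus its folded-in hydrogens.
    """
    coefficients = CROMER_MANN if coefficients is None else coefficients
    el = element.upper()
    if el not in coefficients:
        raise KeyError(f"no Cromer-Mann coefficients for element {element!r}")
    qa = np.asarray(q, dtype=float)
    if np.any(qa < 0):
        raise ValueError("q must be >= 0")
    _check_q_range(qa, allow_wide_q)
    f = coefficients[el].evaluate(qa)
    if n_h:
        if "H" not in coefficients:
            raise KeyError("hydrogen coefficients required for implicit mode")
        f = f + n_h * coefficients["H"].evaluate(qa)
    return f


def excluded_ff(atom: Atom, rho0: float, q: np.ndarray | float) -> np.ndarray | float:
    """Scattering of the solvent displaced by one atom (Gaussian dummy atom).

    f_s(q) = rho0 * V * exp(-q^2 * V^(2/3) / (4 pi)) where V is the atom's
    displaced volume; at q = 0 this is the electron count of the displaced
    solvent, rho0 * V.
    """
    V = atom.displaced_volume
    if V <= 0:
        raise ValueError(
            f"atom {atom.element} has displaced_volume {V}; assign volumes first")
    qa = np.asarray(q, dtype=float)
    out = rho0 * V * np.exp(-qa ** 2 * V ** (2.0 / 3.0) / (4.0 * math.pi))
    return out if out.ndim else float(out)


def water_ff(q: np.ndarray | float, *,
             coefficients: Mapping[str, CromerMannCoefficients] | None = None,
             allow_wide_q: bool = False) -> np.ndarray | float:
    """Form factor of one water molecule: 2 f_H(q) + f_O(q) (10 e at q = 0)."""
    coefficients = CROMER_MANN if coefficients is None else coefficients
    qa = np.asarray(q, dtype=float)
    _check_q_range(qa, allow_wide_q)
    out = 2.0 * coefficients["H"].evaluate(qa) + coefficients["O"].evaluate(qa)
    return out if np.ndim(out) else float(out)


def combined_ff(atom: Atom, solvent: SolventModel,
                q: np.ndarray | float, *,
                coefficients: Mapping[str, CromerMannCoefficients] | None = None,
                allow_wide_q: bool = False) -> np.ndarray | float:
    """Per-atom factor F(q) = f_v - c1 f_s + c2 S_i f_w.

    Waters contribute the bare water factor (no excluded-volume or shell
    term of their own).
    """
    if atom.is_water:
        return water_ff(q, coefficients=coefficients, allow_wide_q=allow_wide_q)
    f = vacuum_ff(atom.element, atom.n_implicit_h, q,
                  coefficients=coefficients, allow_wide_q=allow_wide_q)
    f = f - solvent.c1 * excluded_ff(atom, solvent.rho0, q)
    if solvent.c2 != 0.0 and atom.sasa_fraction != 0.0:
        f = f + solvent.c2 * atom.sasa_fraction * water_ff(
            q, coefficients=coefficients, allow_wide_q=allow_wide_q)
    return f


@dataclass
class FormFactorTable:
    """All per-atom factors tabulated on a q-grid.

    ``vacuum`` and ``excluded`` are (N, Q) arrays, ``water`` is (Q,);
    ``combined`` is the (N, Q) array F_i(q) for the stored solvent model.
    Waters get the water factor in all of vacuum/combined and a zero
    excluded column.
    """

    q_grid: np.ndarray
    vacuum: np.ndarray
    excluded: np.ndarray
    water: np.ndarray
    shell_weight: np.ndarray  # per-atom S_i (0 for waters)
    solvent: SolventModel
    combined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        if q.ndim != 1 or (len(q) > 1 and np.any(np.diff(q) <= 0)):
            raise ValueError("q_grid must be a strictly increasing 1-D array")
        self.q_grid = q
        self.combined = self.combined_for(self.solvent.c1, self.solvent.c2)

    @classmethod
    def from_structure(cls, structure: Structure, q_grid: np.ndarray,
                       solvent: SolventModel | None = None, *,
                       coefficients: Mapping[str, CromerMannCoefficients] | None = None,
                       allow_wide_q: bool = False) -> "FormFactorTable":
        solvent = SolventModel() if solvent is None else solvent
        q = np.asarray(q_grid, dtype=float)
        n = len(structure.atoms)
        fw = np.asarray(water_ff(q, coefficients=coefficients,
                                 allow_wide_q=allow_wide_q), dtype=float)
        vac = np.empty((n, len(q)))
        exc = np.zeros((n, len(q)))
        sw = np.zeros(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # range already checked via fw
            for i, a in enumerate(structure.atoms):
                if a.is_water:
                    vac[i] = fw
                else:
                    vac[i] = vacuum_ff(a.element, a.n_implicit_h, q,
                                       coefficients=coefficients,
                                       allow_wide_q=True)
                    exc[i] = excluded_ff(a, solvent.rho0, q)
                    sw[i] = a.sasa_fraction
        return cls(q_grid=q, vacuum=vac, excluded=exc, water=fw,
                   shell_weight=sw, solvent=solvent)

    def combined_for(self, c1: float, c2: float) -> np.ndarray:
        """F_i(q) for given hydration parameters; (N, Q)."""
        return (self.vacuum - c1 * self.excluded
                + c2 * self.shell_weight[:, None] * self.water[None, :])


def thomson_length(*, codata: bool = False) -> float:
    """Classical electron radius r_e = e^2 / (4 pi eps0 m_e c^2), metres.

    This is the scattering length of a single free electron; it sets the
    absolute scale of X-ray scattering (about 2.818e-15 m).
    """
    if codata:
        qe, me, c, eps0 = (_CODATA["q_e"], _CODATA["m_e"],
                           _CODATA["c"], _CODATA["eps0"])
    else:
        qe, me, c, eps0 = (ELECTRON_CHARGE, ELECTRON_MASS,
                           SPEED_OF_LIGHT, VACUUM_PERMITTIVITY)
    return qe ** 2 / (4.0 * math.pi * eps0 * me * c ** 2)


def amplitude_ratio(detector_distance_m: float, *, codata: bool = False) -> float:
    """Scattered-to-incident amplitude ratio r_e / r at a detector distance.

    For a typical 3 m camera this is of order 1e-15: a single electron
    scatters a vanishingly small fraction of the incident beam.
    """
    if detector_distance_m <= 0:
        raise ValueError("detector distance must be positive")
    return thomson_length(codata=codata) / detector_distance_m


def water_electron_density(mass_density: float = 1.0) -> float:
    """Electron density of water at a given mass density, e/A^3.

    (N_A / 18 g/mol) molecules/g x 10 e/molecule x density g/cm^3,
    converted with 1 cm^3 = 1e24 A^3; 1 g/cm^3 gives 0.334 e/A^3.
    """
    if mass_density < 0:
        raise ValueError("mass density must be >= 0")
    per_cm3 = AVOGADRO / WATER_MOLAR_MASS * WATER_ELECTRONS * mass_density
    return per_cm3 / 1e24


def q_from_angle(theta: float, wavelength: float) -> float:
    """Momentum transfer q = 4 pi sin(theta) / lambda, 1/A.

    ``theta`` is HALF the scattering angle (the full angle is 2 theta),
    ``wavelength`` in Angstrom. Profiles recorded on the s = 2 sin(theta)
    / lambda convention convert via q = 2 pi s.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 4.0 * math.pi * math.sin(theta) / wavelength
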