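"""Deterministic synthetic structures and analytic oracles.

Every engine in this package can be exercised without downloading a
single real structure: toy geometries (atom pairs, lines, rings,
spherical shells, random coils) are generated reproducibly from a seed,
serialise to valid PDB, and have closed-form or brute-force reference
intensities. The oracles here are written from the formulas directly and
never call the engines they validate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from saxskit.structure_io import (
    Atom, Structure, DEFAULT_VDW_RADII, assign_volumes,
)
from saxskit.debye_core import ScatteringProfile

__all__ = [
    "ToySpec",
    "make_toy",
    "two_atom_oracle",
    "noisy_profile",
    "GEOMETRIES",
]

GEOMETRIES = ("pair", "line", "ring", "spherical_shell", "random_coil")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a deterministic toy structure.

    ``scale`` is the characteristic length in Angstrom: pair separation,
    line spacing, ring/shell radius, or random-coil step length. The same
    (spec, seed) pair always yields bit-identical coordinates.
    """

    geometry: str = "pair"
    n_atoms: int = 2
    scale: float = 5.0
    element: str = "C"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; choose from {GEOMETRIES}")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _random_coil(n: int, step: float, seed: int) -> np.ndarray:
    """Self-avoiding-ish walk: fixed step, repels previous atoms to 0.8 step."""
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    min_sep2 = (0.8 * step) ** 2
    for i in range(1, n):
        for _attempt in range(200):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = pos[i - 1] + v
            d2 = np.sum((pos[:i - 1] - cand) ** 2, axis=1) if i > 1 else np.array([np.inf])
            if d2.size == 0 or d2.min() > min_sep2:
                pos[i] = cand
                break
        else:  # pragma: no cover - extremely unlikely
            pos[i] = cand
    return pos


def make_toy(spec: ToySpec) -> Structure:
    """Build the toy structure described by ``spec`` with volumes assigned.

    Random-coil atoms are flagged as C-alpha so the coarse hydration
    models (which key on C-alpha positions) can run on them.
    """
    n, s = spec.n_atoms, spec.scale
    if spec.geometry == "pair":
        pos = np.array([[0.0, 0.0, 0.0], [s, 0.0, 0.0]])
    elif spec.geometry == "line":
        pos = np.column_stack([np.arange(n) * s, np.zeros(n), np.zeros(n)])
    elif spec.geometry == "ring":
        ang = 2.0 * math.pi * np.arange(n) / n
        pos = np.column_stack([s * np.cos(ang), s * np.sin(ang), np.zeros(n)])
    elif spec.geometry == "spherical_shell":
        pos = s * _fibonacci_sphere(n)
    else:  # random_coil
        pos = _random_coil(n, s, spec.seed)

    is_coil = spec.geometry == "random_coil"
    atoms = [
        Atom(element=spec.element, position=p,
             name="CA" if is_coil else spec.element,
             res_name="ALA" if is_coil else "UNK",
             res_seq=i + 1,
             is_calpha=is_coil and spec.element.upper() == "C")
        for i, p in enumerate(pos)
    ]
    st = Structure(atoms=atoms,
                   identifier=f"{spec.geometry}-{spec.n_atoms}-{spec.seed}")
    if spec.element.upper() in DEFAULT_VDW_RADII:
        assign_volumes(st)
    return st


def two_atom_oracle(f: np.ndarray, d: float, q_grid: np.ndarray) -> ScatteringProfile:
    """Closed form of the two-identical-atom Debye sum.

    I(q) = 2 f^2(q) [1 + sin(q d)/(q d)]: two diagonal terms plus the two
    symmetric interference terms. Written directly from the formula, not
    via the Debye engine.
    """
    if d <= 0:
        raise ValueError("separation d must be positive")
    q = np.asarray(q_grid, dtype=float)
    f = np.asarray(f, dtype=float)
    if f.shape != q.shape:
        raise ValueError("f must be tabulated on q_grid")
    x = q * d
    sinc = np.ones_like(x)
    nz = x != 0
    sinc[nz] = np.sin(x[nz]) / x[nz]
    return ScatteringProfile(q=q, intensity=2.0 * f ** 2 * (1.0 + sinc))


def noisy_profile(profile: ScatteringProfile, rel_sigma: float,
                  seed: int) -> ScatteringProfile:
    """Gaussian-noise replica with sigma(q) = rel_sigma * I(q), seeded."""
    if rel_sigma <= 0:
        raise ValueError("rel_sigma must be positive")
    rng = np.random.default_rng(seed)
    sigma = rel_sigma * np.abs(profile.intensity)
    noisy = profile.intensity + rng.normal(scale=sigma)
    return ScatteringProfile(q=profile.q.copy(), intensity=noisy, sigma=sigma)
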