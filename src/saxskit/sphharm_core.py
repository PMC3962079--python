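"""Scattering intensity via a spherical-harmonics multipole expansion.

Expanding the plane-wave phase factor in spherical harmonics turns the
orientational average into a sum of partial amplitudes

    A_Lm(q) = 4 pi i^L sum_j f_j(q) j_L(q r_j) Y*_Lm(omega_j)

where (r_j, omega_j) are polar coordinates of atom j about the expansion
origin, j_L are spherical Bessel functions and Y_Lm orthonormal
(Condon-Shortley) spherical harmonics. Orthogonality kills all cross
terms, leaving

    I(q) = (1 / 4 pi) sum_L sum_m |A_Lm(q)|^2

(the 1/4pi is the solid-angle average that makes a single atom at the
origin give exactly F^2, matching the Debye engine). Evaluation is
O(N L^2) per q point instead of the Debye sum's O(N^2); the price is a
truncation order L_max that must satisfy the Nyquist-type bound
L >= q_max d_max / 2 or systematic errors appear.

This evaluator is deliberately independent of the Debye engines so the
two can cross-check each other.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import spherical_jn, sph_harm_y

from saxskit.structure_io import Structure
from saxskit.formfactor import FormFactorTable
from saxskit.debye_core import ScatteringProfile

__all__ = [
    "MultipoleAmplitudes",
    "partial_amplitudes",
    "intensity_sphharm",
    "per_order_intensity",
    "choose_order",
    "DEFAULT_ORDER",
    "MAX_ORDER",
]

#: Default harmonic order (adequate for small globular proteins at SAXS q).
DEFAULT_ORDER = 15
#: Hard cap on the order; beyond this, numerics and cost degrade.
MAX_ORDER = 50


@dataclass
class MultipoleAmplitudes:
    """Partial amplitudes A_Lm(q) as a dense (L, m, q) complex array.

    ``a_lm[L, m + l_max, :]`` holds A_Lm(q); entries with ``|m| > L`` are
    zero padding.
    """

    l_max: int
    a_lm: np.ndarray       # (l_max+1, 2*l_max+1, Q) complex
    q_grid: np.ndarray
    origin: np.ndarray

    def amplitude(self, L: int, m: int) -> np.ndarray:
        if not (0 <= L <= self.l_max and -L <= m <= L):
            raise IndexError(f"(L, m) = ({L}, {m}) out of range")
        return self.a_lm[L, m + self.l_max]


def _to_polar(positions: np.ndarray, origin: np.ndarray):
    rel = positions - origin
    r = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(r > 0, np.arccos(np.clip(
            np.divide(rel[:, 2], r, out=np.zeros_like(r), where=r > 0),
            -1.0, 1.0)), 0.0)
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    return r, theta, phi


def partial_amplitudes(structure: Structure, table: FormFactorTable,
                       q_grid: np.ndarray | None = None,
                       l_max: int = DEFAULT_ORDER,
                       origin: np.ndarray | None = None) -> MultipoleAmplitudes:
    """Compute every A_Lm(q) up to order ``l_max``.

    The expansion origin defaults to the centre of geometry (convergence
    with L is fastest when the structure is centred). An atom exactly at
    the origin is legal: j_L(0) vanishes for L > 0, so it feeds only the
    monopole.
    """
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    q = table.q_grid if q_grid is None else np.asarray(q_grid, dtype=float)
    if q_grid is not None and not np.array_equal(q, table.q_grid):
        raise ValueError("q_grid must match the form-factor table grid")
    pos = structure.positions()
    if pos.shape[0] == 0:
        raise ValueError("need at least one atom")
    origin = pos.mean(axis=0) if origin is None else np.asarray(origin, float)
    r, theta, phi = _to_polar(pos, origin)
    F = table.combined                       # (N, Q)
    qr = np.outer(q, r)                      # (Q, N)

    a = np.zeros((l_max + 1, 2 * l_max + 1, len(q)), dtype=complex)
    for L in range(l_max + 1):
        jl = spherical_jn(L, qr)             # (Q, N)
        G = F.T * jl                         # (Q, N): f_j(q) j_L(q r_j)
        pref = 4.0 * math.pi * (1j) ** L
        for m in range(-L, L + 1):
            Y = sph_harm_y(L, m, theta, phi)  # (N,)
            a[L, m + l_max] = pref * (G @ np.conj(Y))
    return MultipoleAmplitudes(l_max=l_max, a_lm=a, q_grid=q, origin=origin)


def intensity_sphharm(amps: MultipoleAmplitudes) -> ScatteringProfile:
    """Orientationally averaged intensity from the partial amplitudes.

    I(q) = (1/4pi) sum_{L,m} |A_Lm(q)|^2; normalised so a single atom
    gives F^2(q) and I(0) = (sum_i F_i(0))^2, in agreement with the Debye
    engine.
    """
    I = (np.abs(amps.a_lm) ** 2).sum(axis=(0, 1)) / (4.0 * math.pi)
    return ScatteringProfile(q=amps.q_grid, intensity=I)


def per_order_intensity(amps: MultipoleAmplitudes) -> np.ndarray:
    """Diagnostic: each order's contribution, shape (l_max+1, Q).

    Rows sum to the total intensity; useful for judging convergence of
    the truncation (monopole dominates at low q, higher orders switch on
    as q d_max grows).
    """
    return (np.abs(amps.a_lm) ** 2).sum(axis=1) / (4.0 * math.pi)


def choose_order(q_max: float, d_max: float, *,
                 floor: int = DEFAULT_ORDER, cap: int = MAX_ORDER) -> int:
    """Harmonic order from the Nyquist-type bound L >= q_max d_max / 2.

    Returns at least ``floor`` (default 15) and at most ``cap`` (default
    50); if the bound itself exceeds the cap the truncation cannot be
    made safe and a warning is issued.
    """
    if q_max <= 0 or d_max <= 0:
        raise ValueError("q_max and d_max must be positive")
    nyquist = int(math.ceil(q_max * d_max / 2.0))
    order = max(nyquist, floor)
    if order > cap:
        warnings.warn(
            f"Nyquist bound L >= {nyquist} exceeds the cap {cap}; the "
            f"truncated expansion will be systematically in error",
            stacklevel=2)
        order = cap
    return order
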