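"""Real-space descriptors: p(r), the I(q) <-> p(r) pair, Guinier analysis.

The pair distribution p(r) is the zero-angle-weighted histogram of all
interatomic distances,

    p(r) = sum_{i != j} f_i(0) f_j(0) delta(r - d_ij),

the Fourier mate of the intensity:

    I(q) = 4 pi int p(r) sinc(q r) dr
    p(r) = (1 / 2 pi^2) int I(q) q r sin(q r) dq

p(r) vanishes beyond the largest particle dimension d_max. The Guinier
approximation ln I = ln I(0) - q^2 Rg^2 / 3 holds at low q and yields the
zero-angle intensity (hidden behind the beamstop in a real experiment)
and the radius of gyration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from saxskit.structure_io import Structure
from saxskit.debye_core import ScatteringProfile

__all__ = [
    "PairDistribution",
    "GuinierResult",
    "pair_distribution",
    "intensity_from_pr",
    "pr_from_intensity",
    "guinier_fit",
    "radius_of_gyration",
    "d_max_from_pr",
]


@dataclass
class PairDistribution:
    """f(0)-weighted pair-distance density on a uniform r grid.

    ``rho`` is normalised as a density: 4 pi * integral(rho dr) equals the
    total off-diagonal pair weight. The i == j self terms (zero distance)
    are kept apart in ``self_weight`` so the r > 0 profile stays a true
    interference histogram.
    """

    r: np.ndarray
    rho: np.ndarray
    d_max: float
    self_weight: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.r.shape != self.rho.shape or self.r.ndim != 1:
            raise ValueError("r and rho must be equal-length 1-D arrays")

    def total_weight(self) -> float:
        """Off-diagonal pair weight, 4 pi * integral of rho."""
        return 4.0 * math.pi * float(trapezoid(self.rho, self.r))

    def write_dat(self, path, *, header: str = "") -> None:
        lines = []
        if header:
            lines.extend("# " + h for h in header.splitlines())
        lines.append("# r[A]  p(r)")
        lines.extend(f"{ri:.6e} {pi:.6e}" for ri, pi in zip(self.r, self.rho))
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GuinierResult:
    """Zero-angle intensity and radius of gyration from the Guinier region."""

    i0: float
    rg: float
    fit_range: tuple[float, float]
    r_squared: float
    n_points: int

    def report(self) -> str:
        return (f"I(0)      {self.i0:.6g}\n"
                f"Rg        {self.rg:.6g} A\n"
                f"q_range   {self.fit_range[0]:.6g} .. {self.fit_range[1]:.6g} 1/A\n"
                f"n_points  {self.n_points}\n"
                f"r^2       {self.r_squared:.6f}\n")


def pair_distribution(structure: Structure, f0_weights: np.ndarray,
                      bin_width: float = 0.25) -> PairDistribution:
    """Weighted pair-distance histogram of a structure.

    Each unordered pair contributes 2 f_i(0) f_j(0) (both orderings of the
    double sum); self pairs go to ``self_weight``. The r grid is bin
    centres padded with one empty bin beyond d_max so quadrature sees the
    full mass.
    """
    n = len(structure.atoms)
    if n < 2:
        raise ValueError("pair distribution requires >= 2 atoms")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    w = np.asarray(f0_weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("f0_weights must hold one zero-angle factor per atom")
    d = pdist(structure.positions())
    iu, ju = np.triu_indices(n, k=1)
    pair_w = 2.0 * w[iu] * w[ju]
    dmax = float(d.max())
    n_bins = int(math.floor(dmax / bin_width)) + 2  # trailing empty bin
    idx = np.minimum((d / bin_width).astype(int), n_bins - 2)
    hist = np.bincount(idx, weights=pair_w, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    rho = hist / (4.0 * math.pi * bin_width)
    return PairDistribution(r=centers, rho=rho, d_max=dmax,
                            self_weight=float(np.sum(w * w)))


def intensity_from_pr(pr: PairDistribution,
                      q_grid: np.ndarray) -> ScatteringProfile:
    """Forward transform I(q) = 4 pi int p(r) sinc(q r) dr (+ self terms).

    Trapezoidal quadrature on the uniform r grid; the stored self-pair
    weight enters as a q-independent additive term (sinc(0) = 1), so the
    result matches a Debye sum over the same zero-angle factors.
    """
    q = np.asarray(q_grid, dtype=float)
    s = np.sinc(np.outer(q, pr.r) / np.pi)          # (Q, R)
    I = 4.0 * math.pi * trapezoid(pr.rho[None, :] * s, pr.r, axis=1)
    I = I + pr.self_weight
    return ScatteringProfile(q=q, intensity=I)


def pr_from_intensity(profile: ScatteringProfile,
                      r_grid: np.ndarray) -> PairDistribution:
    """Inverse transform p(r) = (1/2 pi^2) int I(q) q r sin(q r) dq.

    The integral needs the intensity to have decayed by the end of the
    measured q-range; a warning is issued otherwise. The self-pair
    (r = 0) mass cannot be separated by the inverse transform and is left
    at zero.
    """
    q = profile.q
    I = profile.intensity
    if I[-1] > 0.05 * I.max():
        warnings.warn(
            "intensity has not decayed at q_max; the inverse transform "
            "will be truncated", stacklevel=2)
    r = np.asarray(r_grid, dtype=float)
    qr = np.outer(r, q)                              # (R, Q)
    integrand = I[None, :] * q[None, :] * np.sin(qr) * r[:, None]
    rho = trapezoid(integrand, q, axis=1) / (2.0 * math.pi ** 2)
    d_max = d_max_from_pr(r, rho)
    return PairDistribution(r=r, rho=rho, d_max=d_max, self_weight=0.0)


def d_max_from_pr(r: np.ndarray, rho: np.ndarray,
                  threshold: float = 1e-9) -> float:
    """Largest dimension: where p(r) has dropped to (numerically) zero.

    Operationally the first grid point after the global maximum where the
    density falls below ``threshold`` of the total mass per bin.
    """
    rho = np.asarray(rho, dtype=float)
    total = float(np.abs(rho).sum())
    if total == 0.0:
        return 0.0
    peak = int(np.argmax(rho))
    below = np.nonzero(np.abs(rho[peak:]) < threshold * total)[0]
    if len(below) == 0:
        return float(r[-1])
    return float(r[peak + below[0]])


def radius_of_gyration(structure: Structure,
                       weights: np.ndarray | None = None) -> float:
    """Coordinate-space radius of gyration, optionally electron-weighted."""
    pos = structure.positions()
    n = pos.shape[0]
    if n == 0:
        raise ValueError("empty structure")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or w.sum() <= 0:
        raise ValueError("weights must be positive per-atom values")
    center = (w[:, None] * pos).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((pos - center) ** 2).sum(axis=1)).sum() / w.sum()))


def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.3,
                min_points: int = 5, max_iter: int = 30) -> GuinierResult:
    """Linear fit of ln I against q^2 in the self-consistent Guinier window.

    Starting from the lowest-q third of the profile, fit ln I = ln I(0)
    - (Rg^2 / 3) q^2, then shrink/grow the window to q Rg <= ``qrg_limit``
    and refit until the window stabilises. Requires at least
    ``min_points`` strictly positive intensities in the window and a
    negative slope (otherwise there is no Guinier region).
    """
    q = profile.q
    I = profile.intensity
    if len(q) < min_points:
        raise ValueError("profile too short for a Guinier fit")

    def _fit(n_pts: int):
        qq, II = q[:n_pts], I[:n_pts]
        if np.any(II <= 0):
            raise ValueError("non-positive intensity in the Guinier window")
        res = linregress(qq ** 2, np.log(II))
        if res.slope >= 0:
            raise ValueError("no Guinier region: ln I does not decrease in q^2")
        rg = math.sqrt(-3.0 * res.slope)
        return rg, math.exp(res.intercept), res.rvalue ** 2

    n_pts = max(min_points, len(q) // 3)
    for _ in range(max_iter):
        rg, i0, r2 = _fit(n_pts)
        q_limit = qrg_limit / rg
        new_n = int(np.searchsorted(q, q_limit, side="right"))
        new_n = max(min_points, min(new_n, len(q)))
        if new_n == n_pts:
            break
        n_pts = new_n
    rg, i0, r2 = _fit(n_pts)
    return GuinierResult(i0=i0, rg=rg, fit_range=(float(q[0]), float(q[n_pts - 1])),
                         r_squared=r2, n_points=n_pts)
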