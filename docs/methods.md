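# Methods

This note records the models implemented in `saxskit`, the assumptions
behind them, the defaults and why they were chosen, and what the test
suite does and does not establish.

## Scattering model

The momentum-transfer convention is q = 4π sin θ / λ with 2θ the
scattering angle, in Å⁻¹ throughout. Profiles recorded on the
s = 2 sin θ / λ convention can be converted with q = 2πs. Coherent
elastic scattering only; the polarization factor and incoherent
scattering are outside the model (at small angles the polarization
factor is ≈ 1). The absolute scale of electron scattering is set by the
Thomson length r_e = e²/(4πε₀ m_e c²) ≈ 2.818×10⁻¹⁵ m; the package
reproduces this and the scattered-to-incident amplitude ratio at a
typical 3 m detector distance (~10⁻¹⁵) from embedded constants. Two
constant sets are available: a compact historical set used for the
reproduced numbers (electron mass 9.107×10⁻³¹ kg) and CODATA 2018
behind a `codata=True` flag.

### Atomic form factors

Vacuum factors use the International-Tables 4-Gaussian + constant
(Cromer–Mann) parameterisation; coefficients for H, C, N, O, Na, Mg, P,
S, Cl, K, Ca, Mn, Fe and Zn are embedded and validated at import time
(|f(0) − Z| < 0.1 e). The parameterisation is well validated up to
q ≈ 0.33 Å⁻¹; the package warns beyond that and refuses q > 6 Å⁻¹
unless overridden (a 6-Gaussian wide-angle set would be needed there; a
hook exists but constants are not embedded). Crystal structures rarely
resolve hydrogens, so the default mode folds standard per-atom-name
hydrogen counts into each heavy atom's factor; an explicit-hydrogen mode
keeps H records as scatterers.

The excluded solvent is the Gaussian dummy-atom model:
f_s(q) = ρ₀ V exp(−q² V^{2/3}/4π), with V = (4/3)π r_vdw³ from
Bondi-style radii (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å;
overridable). ρ₀ defaults to 0.334 e/Å³, the electron density of pure
water, which the package derives from Avogadro's number, 10 e per
molecule, 18 g/mol and 1 g/cm³.

The combined per-atom factor is F = f_v − c1·f_s + c2·S_i·f_w with
f_w = 2f_H + f_O (10 e at q = 0). c1 rescales the excluded-volume
contrast (fitting grid 0.95–1.12); c2 weights a hydration-shell term
proportional to the atom's solvent-accessible fraction S_i (grid 0–4).
S_i is stored as a fraction in [0, 1]; the absolute exposed area in Å²
is kept alongside, since conventions differ in the field.

### SASA

Shrake–Rupley with probe 1.4 Å and 960 test points by default. The test
points are golden-spiral points on a hemisphere plus their antipodes,
making the set exactly centrosymmetric so mirror-symmetric environments
receive identical exposed counts; fractions change by < 1% when the
point count doubles. Radii must be assigned first; an isolated atom is
fully exposed by construction.

## Engines

**Exact Debye.** The full double sum with sin(x)/x evaluated by the
library sinc (exact limit 1 at x = 0, so the diagonal and q → 0 are
handled without branches). Pairs are processed in chunks of ~2×10⁶ to
bound memory. I(0) = (Σ F_i(0))² holds exactly and the sum is invariant
under rigid motion to ~10⁻¹⁵ relative.

**Row-partial decomposition.** Row i's partial sum runs over all
columns; summing each row's partial exactly once reproduces the double
sum, so disjoint row blocks can be computed independently and
accumulated in any order. The accumulator enforces a disjoint, complete
cover and this contract is exercised with randomised partitions (exact
to ~10⁻¹⁴). No device code is included; the decomposition is the
backend-agnostic contract a GPU or multiprocess backend would rely on.

**Distance-binned mode.** Valid when all scatterers share one factor
(then F_iF_j = F² leaves the sum): I = F²(N + 2 Σ_k m(r_k) sinc(q r_k))
with distances quantised to d_max/n_bins (default 100 bins), floor
binning, right-open bins, r = d_max in the last bin, bin centres as
representatives. The diagonal term uses I_j = F², consistent with the
N²F² zero-angle limit. Binning is a quantisation: the error per pair is
O((q·Δ)²) but its sign depends on where distances fall within bins, so
on random structures the error as a function of n_bins decreases in
trend while individual steps can fluctuate (phase luck). The canonical
convergence fixture is therefore a deterministic 100-atom ring of
radius 20 Å, where the error falls monotonically over
n_bins ∈ {25, 50, 100, 200} and the 100-bin deviation from the exact
engine stays below 3% (max relative, q ≤ 0.33 Å⁻¹); random-coil
fixtures at 100 bins land near 1–2% but without guaranteed step-wise
monotonicity.

**Modulated mode.** All atoms keep their zero-angle factor and share
one Gaussian modulation, I(q) = e^{−bq²} Σ f_i(0) f_j(0) sinc(q r_ij),
default b = 0.23 Å². (b is sometimes quoted in Å⁻¹, but
E²(q) = exp(−bq²) is only dimensionless for b in Å²; Å² is used here.)
This approximates the *vacuum* factor decay well — within ~0.3% of the
exact engine for carbon structures over q ≤ 0.33 — but must not be used
near zero contrast: when solvent subtraction drives the combined F(q)
through zero the relative error is unbounded, which is a property of
the approximation, not a defect of the implementation.

**Spherical harmonics.** Partial amplitudes
A_Lm(q) = 4π i^L Σ_j f_j(q) j_L(q r_j) Y*_Lm(ω_j) with orthonormal
(Condon–Shortley) harmonics and scipy's spherical Bessel functions.
Summing |A_Lm|² over L, m gives 4π F² for a single atom at the origin,
so a 1/(4π) solid-angle-average factor is applied to make the evaluator
agree with the Debye engine exactly in that limit; the choice is pinned
by the Debye-agreement requirement. The expansion origin defaults to
the centre of geometry (convergence is fastest for a centred
structure) and is configurable. The truncation order comes from the
Nyquist-type bound L ≥ q_max·d_max/2 with floor 15 and cap 50; a
warning is issued when the bound itself exceeds the cap, because the
truncation then carries systematic error. For real form factors the
amplitudes obey A_{L,−m} = (−1)^{L+m} conj(A_{L,m}) — note the extra
(−1)^L from the i^L prefactor — and centrosymmetric structures have
vanishing odd-L terms. Against the exact Debye engine the evaluator
agrees to better than 0.1% on ≤50-atom fixtures over q ≤ 0.5 at the
Nyquist order.

## Hydration shell (explicit)

Waters are placed on an FCC lattice of edge l_cell: the corner
sublattice plus three face-centred sublattices, generated without
duplicates (a 10⁻⁶ Å snap guards degenerate inputs). A single cell has
the canonical 14 distinct points; effective occupancy is
8·(1/8) + 6·(1/2) = 4 waters (40 e) per cell, so the shell's excess
density is δρ = 40/l_cell³. The default l_cell = 11 Å puts δρ at
≈ 0.030 e/Å³, a commonly assumed hydration-shell contrast; the edge
length is the knob that controls shell density and is exposed in the
CLI. The lattice is anchored at the structure's bounding-box minimum
minus the 6.5 Å outer cutoff (the registration is otherwise arbitrary
and does not affect retained-water statistics materially). Lattice
points whose nearest-Cα distance lies in [3.5, 6.5] Å become water
scatterers carrying f_w; the combined protein + water set then goes
through the exact Debye sum. Coincident scatterers are legal (sinc
limit). A lone water's intensity is f_w², i.e. (2f_H + f_O)².

## Real-space transforms

The pair distribution is the f(0)-weighted histogram of interatomic
distances, p(r) = Σ_{i≠j} f_i(0) f_j(0) δ(r − d_ij), stored as a
density on a uniform grid of bin centres (default 0.25 Å) with one
trailing empty bin so quadrature captures the full mass; self pairs are
kept separately. Forward and inverse transforms implement the Fourier
pair I(q) = 4π∫ p(r) sinc(qr) dr and
p(r) = (1/2π²)∫ I(q) q r sin(qr) dq with trapezoidal quadrature. The
inverse needs the intensity to have decayed by q_max (warned
otherwise); on band-limited synthetic input the round trip reproduces
p(r) with relative L2 error below 10⁻⁴ (measured ~4×10⁻⁸) and d_max —
operationally the first point after the global maximum where p(r)
falls below 10⁻⁹ of its total mass — within one bin. The histogram +
forward-transform route agrees with the direct zero-angle-weighted
Debye sum to better than 1% at 0.05 Å bins (the residual is binning
error).

Guinier analysis fits ln I against q² over a self-consistent low-q
window with q·R_g ≤ 1.3 (the standard-practice bound, configurable),
starting from the lowest-q third of the profile and iterating the
window until stable; it requires ≥ 5 strictly positive points and a
negative slope ("no Guinier region" otherwise). R_g = sqrt(−3·slope),
I(0) = exp(intercept). On an ideal Gaussian profile both are recovered
to 4+ significant figures; on computed vacuum-factor profiles of coil
fixtures the Guinier R_g matches the electron-weighted coordinate R_g
within 5% (contrast-subtracted profiles can have negative per-atom
weights, for which a "mass-weighted" coordinate R_g is not defined —
comparisons use vacuum factors).

## Fitting

χ = sqrt((1/M) Σ ((I_exp − c·I_calc)/σ)²). The square root is applied
by default; `squared=True` reports the χ² convention (both appear in
the literature and the difference matters when comparing scores across
tools). c has the closed form Σ(I_exp I_calc/σ²)/Σ(I_calc²/σ²). The
(c1, c2) search is exhaustive over inclusive-endpoint grids built as
integer index × step (avoiding float drift): 35 × 41 = 1435
combinations by default. Ties break toward (1, 0), the physically
neutral point. Computed profiles are evaluated directly on the
experimental q-grid; when grids differ the computed curve is linearly
interpolated and points outside its range dropped with a warning.
Profiles lacking a σ column get σ = 0.01·I with a loud warning.

Because F is affine in (1, c1, c2), the Debye intensity is an exact
quadratic form in six cross sums of the three factor components
(vacuum, excluded, SASA-weighted water). The grid search precomputes
those six profiles in one O(N²) pass and assembles every grid point's
I(q) exactly from them — bit-for-bit the same result as rerunning the
double sum (a `direct` mode that does rerun it is kept and pinned to
the fast path by a test). This keeps the full default grid on a
500-atom structure at ~2 s.

### Identifiability

Noiseless self-fits recover the generating (c1, c2) exactly with χ ≈ 0.
With noise the three fitted parameters are strongly correlated: c
absorbs overall scale, and the spectral shapes that distinguish c1 from
c2 are subtle. A Cramér–Rao analysis at the package's study conditions
(500-atom coil, 101 points over 0–0.5 Å⁻¹, σ = I/50, c and the other
parameter profiled out) gives best-achievable standard errors
σ_c1 ≈ 0.05 (ten grid steps) and σ_c2 ≈ 0.22 (two grid steps). At that
noise level the grid minimum therefore wanders several c1 steps from
the truth no matter how the minimisation is done; the scale c is
recovered to well under 1%. Users should treat fitted c1 from a single
noisy profile as soft, and c2 as meaningful only to ~±0.2.

## Synthetic data

The fixture generator produces atom pairs, lines, regular rings,
Fibonacci spherical shells, and random coils (fixed 3.8 Å steps — the
Cα–Cα virtual bond length — with a 0.8-step self-avoidance repulsion),
deterministically from integer seeds (NumPy PCG64, no global state).
These capture the geometric content of the engines (distances, shapes,
symmetry) but none of real protein chemistry: no side-chain packing, no
heteroatom composition gradients, no disorder, and coil fixtures are
far more extended than folded proteins. Passing tests therefore
establish the correctness of the scattering mathematics and the solvent
bookkeeping, not the physical accuracy of hydration defaults on real
data, which must be judged against experimental profiles.

## Numerical choices and degenerate inputs

sinc via numpy (exact at 0); distances via scipy's pdist; an atom at
the spherical-harmonics origin feeds only the monopole (j_L(0) = δ_L0);
all-coincident structures are legal in the histogram (single zero
bin); single-atom structures are legal everywhere except d_max, the
histogram and p(r), which require two atoms; altloc records keep the
highest occupancy (first on tie); only the first MODEL of multi-model
PDBs is read; HETATM waters are flagged and scatter as f_w.

## Known limitations

- No mmCIF, assemblies, or symmetry expansion.
- Anomalous/resonant corrections and the 6-Gaussian wide-angle factor
  set are not implemented.
- The explicit-shell model keys on Cα atoms and uniform shell contrast;
  no per-residue effective factors, envelope construction, or explicit
  water-box averaging.
- No indirect Fourier transform with smoothness regularisation; the
  plain inverse transform needs decayed intensities.
- The parallel decomposition ships with a serial executor only.
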