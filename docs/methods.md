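# Methods

## Dose model

Each principal-axis relative dose profile of a single Gamma Knife
Perfexion shot is fitted by an erf-sum

    D(k) = Σ_{i=1..n} A_i · erf((k + a_i) / b_i) + C0,

with amplitudes `A_i` (%), shifts `a_i` (mm; the i-th transition sits at
k = −a_i) and strictly positive widths `b_i` (mm). Term counts follow the
shapes of the vendor-style profiles: n = 4 for every x/y profile, n = 5
for the z profiles of the 16 and 8 mm collimators (whose asymmetry about
the XY plane stems from the source distribution being rotationally
symmetric about z only), and n = 2 for the nearly symmetric 4 mm z
profile. x/y profiles are assumed perfectly symmetric: only k ≥ 0 data
enter the fit and the model is evaluated at |k|, which enforces
f(k) = f(−k) exactly. The z profile is fitted over its full range with one
global erf-sum (no separate per-side constraints); this is the simplest
reading consistent with a single analytic expression per axis.

The three fitted profiles are composed into the 3D field with
squared-direction-cosine weights: for displacement Δr from the shot
center, ρ = |Δr|,

    D(r) = Σ_{k∈{x,y,z}} D_k(s_k·ρ) · (Δk/ρ)²,

each profile center-normalized to 1. The published rendering of this
composition is typographically ambiguous about whether the profiles take
the radial distance or the coordinate component as argument; we adopt the
radial-distance (direction-cosine interpolation) reading because it
reduces exactly to each 1D profile on its axis, makes XY cross-sections
circular whenever the x and y profiles coincide and XZ sections elliptical
(the observed field geometry), and yields exactly 1 everywhere for uniform
profiles (the weights sum to 1). The z profile takes the *signed* argument
s_z = sign(Δz), propagating its asymmetry to the two hemispheres; for the
symmetric x/y profiles the sign is irrelevant. At ρ = 0 the model returns
1 by definition, avoiding 0/0; it is continuous there.

## Fitting

`fit_profile` runs trust-region least squares with a deterministic
physics-informed start — transitions at the 50 % crossing, widths from the
80–20 penumbra distance divided by 2·erfinv(0.6), amplitudes splitting the
plateau-to-tail height, offset from the tail level — plus seeded
log-normal-jittered restarts (5 by default); the lowest-cost solution
wins. The erf-sum parameterization is degenerate (term permutations,
compensating amplitude structures), so fit quality is judged on the
predicted curve (R², max/rms residual), never on raw parameters. A
constant curve raises (R² undefined); if no restart converges the
best-so-far model is returned with `success = False`.

## Detector geometry

Active volumes are modelled as: ionization chambers = cylindrical cavity
(radius r, length L) plus an optional hemispherical cap of radius r on the
tip minus a coaxial flat-ended electrode cylinder entering from the stem
end; diodes, the diamond and scintillator fibers = disks; one rectangular
diode = box. The long axis is parallel to the device z axis and the
*volume centroid* of the active volume sits at the field center — the
natural reading of "geometric center"; for disks and boxes this equals
the bounding-box center, for capped chambers it is computed in closed form
from the signed cylinder/cap/electrode pieces. Per-detector reference-
point offsets are not modelled (they default to zero).

Exact cavity drawings are not public. The shipped library encodes
dimensions that satisfy every published constraint simultaneously —
nominal active volumes (within manufacturer rounding, ≤10 %), the 5 mm
length and 2.5 length-to-diameter ratio of the long small-cavity chamber,
the 3.6 mm length and 0.9 ratio of the compact one, the 1.23 ratio of the
compact small-cavity chamber, the 2.2 mm × 1 µm diamond disk, and the
exact 1 mm ∅ × 1/3 mm scintillator fibers — and flags each entry
`approximate` where the drawing is under-determined. The library is a YAML
file users can override wholesale. Electrode tips are flat (the drawings
do not resolve the tip shape); boundary points count as inside (measure
zero, fixed for determinism). Wall, stem, density and response weighting
are deliberately outside scope: detectors are treated as ideally and
isotropically responsive, so only geometry matters.

## Quadrature

k_vol = 1 / mean(D_norm) with the mean computed by composite Simpson
quadrature, 100 steps per spatial direction by default (≈10⁶ cells), which
resolves k_vol to the third decimal (step-doubling changes it by <5·10⁻⁴
on the steepest fixture field). Bodies of revolution integrate in
cylindrical coordinates (z, ρ, φ) piecewise over the smooth cylinder /
cap / electrode sub-domains, with ρ mapped to a fixed unit grid
u = ρ/ρ_max(z); this keeps the domain boundary exact and preserves
Simpson's convergence order, which a Cartesian bounding box with an
inclusion mask would destroy. The electrode enters as a negative signed
integral. Boxes integrate on a Cartesian tensor grid. An independent
uniform-random Monte Carlo mean over the same active volume (10⁶ points,
fixed seed) guards the quadrature in the test suite (agreement within
10⁻³).

Ratios chain at full precision; rounding (half away from zero, 3 decimals)
is applied only at reporting. The TRS-483 field output correction factors
k_Q ship as package constants with N.A. cells preserved and propagated
through the table as N.A. A small set of published ratio/k cells do not
reproduce from the printed 3-decimal inputs (the source evidently chained
unrounded intermediates); they are listed in the shipped
`inconsistent_cells` config and excluded from arithmetic cross-checks
rather than forced.

## Model validation statistic

R_v compares summed point doses over isodose-bounded volumes:
membership (dose ≥ level) is decided by the *reference* dose value, the
same point subset feeds both the reference and the model sum (the
integral is approximated by the point sum, as in the source procedure, and
the sum is unweighted — point-density weighting is not applied), and

    R_v = (D_ref − D_model) / D_ref · 100 %.

R_v is therefore exactly zero when the reference doses come from the model
itself, and invariant under common rescaling of both dose sets.

## Synthetic data

The vendor's Monte Carlo profiles and the treatment planning system's
point exports are proprietary, so generators emulate them: profiles are
two-erf flat-tops (rising/falling penumbra), scaled to max 100, with
seeded Gaussian noise (default 0.1 %, the sub-percent statistical level of
MC profile data); z-axis asymmetry is modelled as unequal ± penumbra
widths, strongest at 16 mm (skew 0.15) and nearly gone at 4 mm (0.02),
mirroring how the asymmetry shrinks with field size. Default x/y FWHMs
equal the nominal 16/8/4 mm collimator designations (the designation is
the 50 % isodose diameter); the z FWHM is 0.85 of that, reflecting the
shorter device-axis profile; 80–20 penumbrae default to 2.0/1.4/1.0 mm for
16/8/4 mm, consistent with the up-to-80 %/mm gradients of these fields.
Reference point sets are rejection-sampled in the 19–99 % dose range with
z snapped to a 1 mm grid and default counts of 1700/783/378 points for
16/8/4 mm; an optional multiplicative bias emulates model–TPS
disagreement.

What a green test does **not** establish: the synthetic profiles have
near-zero tails outside the penumbra, whereas real MC profiles carry
percent-level scatter tails, so fixture-field k_vol magnitudes for large
chambers at 4 mm exceed the published ones; fits with the standard term
counts reaching R² ≥ 0.999 on synthetic data show the fitting machinery
reaches the published quality regime, not that it would on vendor data.
The published k_vol table is reproduced only at the level of its internal
arithmetic (ratio and k chains from printed inputs), which is exact.

## Numerical choices

- `steps_per_axis` must be even (composite Simpson); odd values raise.
- Isodose points: bisection along rays to |D − level| < 10⁻⁶.
- Monte Carlo volume/mean oracles: `numpy` PCG64 with explicit seeds.
- Degenerate inputs: empty isodose selections, non-positive ratio inputs,
  k_Q ≤ 0 and constant profiles raise `ValueError`; a non-positive mean
  dose (impossible for valid fields) raises `RuntimeError`.
- The suitability band [0.95, 1.05] is inclusive at both ends.

## Limitations

Single shot at the frame origin with γ = 90° only; no multi-shot
superposition, no phantom-surface or heterogeneity effects, no fluence or
spectral perturbations (k_vol is one factor of k_Q, not all of it), and no
interface to any treatment planning system.
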