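# Methods

`graftmech` is a desk-scale model of the computational–experimental chain
used to study mechanoregulation in arteriovenous grafts (AVGs): compute
wall-mechanics metrics from time-resolved wall data, produce pulsatile
hemodynamics with a 0D surrogate of the AVG loop, translate target shear
stresses into bioreactor operating conditions through measured rheology,
and analyze the in vitro readouts. This note records the models, their
assumptions, the defaults, and the numerical choices.

## Wall metrics (`graftmech.metrics`)

Per surface element over one cardiac cycle of duration `T`:

- **TAWSS** `= (1/T) ∫₀ᵀ ||τ(t)|| dt` (Pa), the time-averaged magnitude of
  the wall shear stress vector.
- **OSI** `= ½(1 − ||∫₀ᵀ τ dt|| / ∫₀ᵀ ||τ|| dt)`, 0 for unidirectional and
  0.5 for purely oscillatory WSS. An element with identically zero WSS has
  an undefined OSI (the denominator vanishes) and is reported as missing,
  never as 0. Values are clipped into [0, 0.5] only to absorb
  floating-point excursions below 1e−9.
- **Wall strain** `ε = sqrt((A_n − A_0)/A_0)` evaluated per time instant
  from element areas and then time-averaged over the cycle. The formula is
  implemented exactly as written; note that it does *not* reduce to
  engineering strain for small equibiaxial deformations, so no such
  equivalence is asserted anywhere. Instants with `A_n < A_0` have no real
  strain under this metric; the default policy clamps the deficit to zero
  with a warning, and a strict mode raises instead.

All cycle integrals use the composite trapezoid rule on the supplied time
grid, with no resampling. For smooth periodic waveforms sampled uniformly
over a full period this is spectrally accurate; for waveforms with jumps,
exactness requires grid points straddling the discontinuity (the tests
construct such grids and compare against exact segment-sum oracles).

Distribution summaries use the linear-interpolation empirical quantile
(`numpy.percentile` default), which also defines the percentile-window
membership test used to decide whether a candidate bioreactor load falls
inside, e.g., the 15th–100th percentile band of the computed metric
distribution.

## 0D circulation surrogate (`graftmech.circulation`)

The full 3D CFD/FSI solves that produced the reference AVG metrics are out
of scope at desk scale; the surrogate is a lumped-parameter loop producing
pulsatile flow and pressure with the right structure and magnitudes:

```
inlet ──R_artery── node A ──R_graft── node V ──R_vein── ground (P = 0)
                     │                   │
                  R1–C–R2             R1–C–R2
                 (distal art.)      (distal ven.)
```

A prescribed positive pulsatile inlet flow (truncated Fourier series,
default mean 1.5 L·min⁻¹, pulsatility index 0.8, 3 harmonics, 1 s period)
enters through the arterial segment; the proximal venous outlet is held at
zero pressure; the two anastomosis nodes each feed a three-element
Windkessel (six lumped elements in total) standing in for the peripheral
bed and collateral venous flow. Segment resistances are Poiseuille,
`R = 8μL/(πr⁴)`, with the study calibers: artery 6.6 mm, vein 7.7 mm,
graft 6 mm diameter, and nominal access-loop lengths (10, 30, 20 cm).
Blood is Newtonian with kinematic viscosity 3.3·10⁻⁶ m²/s and density
1060 kg/m³. **Terminal element values are plausible defaults for an
upper-limb access circulation and are not measured quantities**; they are
chosen so that most inflow crosses the low-resistance graft, as in a
functioning access.

The two capacitor pressures are the only states; node pressures follow
from a 2×2 linear solve each evaluation. Integration uses LSODA
(rtol 1e−9) cycle by cycle until the maximum cycle-to-cycle node-pressure
change falls below 0.1% (relative); the converged last cycle is returned.
Zero-compliance terminals degenerate to series resistors, making the
network a pure resistor algebra (used as an oracle in the tests).

Segment WSS is quasi-static Poiseuille, `τ(t) = 4μQ(t)/(πr³)`, directed
along the segment axis — a deliberate simplification (no Womersley
profile, no flow separation, no spatial variation over the anastomosis).
The surrogate is therefore checked only against order-of-magnitude
consistency: with 1–2 L·min⁻¹ through the 6 mm graft, graft TAWSS falls in
2–8 Pa, the range around the reference value of ~5 Pa from the
patient-specific CFD. It cannot and does not reproduce the spatial
TAWSS/OSI maps of a 3D solve.

## Rheology and bioreactor design (`graftmech.rheology`, `graftmech.bioreactor`)

Viscosity is measured (or generated) on a cone-plate grid from 10 to
1500 s⁻¹, six points per decade. Replicate measurements are averaged per
shear-rate level *before* interpolation; viscosity at an applied shear
rate is then a piecewise-linear interpolation between bracketing levels
(in linear shear-rate space by default; a log-space flag exists since the
grid is log-spaced). Extrapolation raises in strict mode and falls back to
the nearest endpoint with a warning otherwise. Wall shear stress is
`τ(γ̇) = γ̇·η(γ̇)`.

Daily applied-load reporting multiplies the daily mean shear rate by the
daily mean viscosity; its standard deviation uses first-order propagation
for independent factors, `σ_τ = sqrt((η̄ σ_γ̇)² + (γ̇̄ σ_η)²)`. Independence
and first-order expansion are assumptions; correlated rate/viscosity
fluctuations would not be captured.

The culture chamber is a concentric annulus: construct outer surface at
R1 = 1.7 mm (3 mm inner-diameter scaffold, 200 µm wall, on silicone
tubing) and glass wall at R2. The glass-tube radius is not a measured
quantity; the default gap is 2.0 mm and every design output records the
geometry used. A constant axial pressure gradient G drives laminar flow:

- *Newtonian*: the classical annular Poiseuille profile
  `u(r) = (G/4μ)[R2² − r² + (R2² − R1²)·ln(r/R2)/ln(R2/R1)]` with analytic
  wall shear rates, a flow-rate closed form, and a gap Reynolds-number
  warning above 2000.
- *Generalized Newtonian*: momentum balance gives
  `τ(r) = (G/2)(r_m² − r²)/r` with the zero-stress radius r_m the single
  unknown; no-slip at both walls is enforced by shooting on r_m (Brent
  root-find on the net velocity built by Simpson quadrature of γ̇(r), 801
  nodes per side). The constitutive inversion γ̇(τ) is closed-form for
  power-law fluids and a log-log table guess polished by damped Newton
  iteration otherwise. The Newtonian special case agrees with the analytic
  solution to better than 1e−6 relative.

Inverse design root-finds G so the inner-wall stress equals the target
(high ≈ 3.2 Pa, low ≈ 0.44 Pa). Oscillatory conditions (complete flow
reversal at 1 Hz) use quasi-static alternation: a square-wave gradient of
the designed amplitude, with the gap Womersley number
`α = (gap/2)·sqrt(ωρ/μ)` reported as a validity diagnostic — α of order 1
means the quasi-static assumption is mildly strained near reversals. Full
Womersley annular dynamics are a known limitation, not modeled. The
generated oscillatory stress series places τ = 0 exactly at the reversal
instants so that the signed trapezoidal cycle integral vanishes and the
series' OSI is exactly 0.5.

## Readout analysis (`graftmech.qpcr`, `assays`, `orientation`, `stats`)

**qPCR.** Reactions carry two technical replicates. Exclusion rules, in
order: failed melting curve; replicate spread > 0.5 Ct; blanco
(no-template control) Ct less than a margin above the replicate-mean
signal Ct. The blanco margin is not specified by any measured protocol
figure; the default is 3 cycles (≈ 8-fold separation) and is
configurable. Filtering is total and idempotent, and each excluded row
carries a machine-readable reason. ΔCt subtracts the housekeeping gene
(GAPDH) per sample from the replicate-mean Ct; ΔΔCt subtracts the control
group's (low-shear condition) per-gene mean ΔCt — mean by default, median
by flag, since percentile-based displays make either defensible; fold
change is `2^−ΔΔCt`. By construction the control group's geometric mean
fold is exactly 1, and its arithmetic mean is 1 on noise-free data.

**Assays.** DNA/GAG/HYP per dry mass; total construct surface
= length × circumference = 15 mm × 1.5π mm ≈ 70.69 mm²; per-construct DNA
= (DNA/mass)·(mass/surface)·total surface; growth = day-14 mass/surface
over the pre-seeding baseline (1.0 = no change), tested against 1.0 with a
one-sample t-test.

**Fiber orientation.** The original in-house orientation software is not
published, so orientation analysis is built on the standard structure
tensor: Gaussian pre-smoothing (σ = 1 px), gradient outer products
averaged in a Gaussian window (σ = 4 px), fiber direction = eigenvector of
the smaller eigenvalue, angles axial on [0°, 180°) with 36 bins of 5°. The
histogram weights each pixel by coherence × tensor energy: coherence alone
leaves near-flat background pixels (whose orientation is numerically
meaningless noise) with non-negligible weight, while the energy factor
suppresses them. Dispersion is the circular standard deviation of the
doubled angles (the standard treatment of axial data). On isotropic-noise
images the histogram is near-uniform but carries finite-sample
fluctuation; stability checks use images of at least 512² pixels or
several hundred fibers.

**Statistics.** Group comparisons use the tie-corrected Kruskal–Wallis
test followed by Dunn's pairwise z-tests on pooled mean ranks (tie
correction `Σ(t³−t)/(12(N−1))`), Holm-adjusted by default (the adjustment
flavor of a "Dunn's multiple comparison test" varies between packages and
is configurable). Fold changes are log10-transformed before testing; the
rank statistics are invariant to this monotone transform, and it is
applied for fidelity to the reporting pipeline. All-identical data return
H = 0, p = 1 rather than an error. Significance is declared at p < 0.05.

## Synthetic data (`graftmech.synth`)

Generators are seeded (`numpy.random.default_rng`) and bit-identical for
identical arguments. Each one's ground truth is recoverable by the
corresponding analysis operation (the round-trip suite):

- **WSS series**: offset sinusoid `s·(a + b sin(2πt/T))·x̂` with the
  offset solved by Brent iteration *on the output grid* so the trapezoidal
  TAWSS and OSI equal the request to ~1e−14; the family covers OSI
  ∈ [0, 0.5] (b = 0 gives 0, a = 0 gives 0.5). Element-level jitter is
  multiplicative on the amplitude, perturbing TAWSS but never OSI.
- **Area series**: raised-sine instantaneous strain
  `ε(t) = ε̄(1 − cos 2πt/T)` (defaults ε̄ = 1% with 2% peaks, the magnitudes
  computed for the venous anastomosis) with `A_n = A_0(1 + ε²)` so the
  square-root metric inverts exactly.
- **Rheology**: Carreau (blood-like parameters) or power-law viscosities
  on the 10–1500 s⁻¹ grid, rescaled so the *linear interpolant* of the
  noise-free grid passes exactly through the blood-matching calibration
  point η(200 s⁻¹) = 4·10⁻³ Pa·s; multiplicative lognormal noise with
  prescribed CV, mean-one.
- **Ct tables**: gene Ct = housekeeping Ct + control ΔCt − log2(fold), so
  planted folds invert exactly; contamination injects the three
  quality-control violations at a prescribed rate.
- **Fiber images**: anti-aliased line segments with doubled-angle
  von-Mises orientations, Gaussian blur, additive noise.
- **Inlet waveform**: positive truncated-Fourier pulse with exact mean and
  requested pulsatility index; infeasible (non-positive) requests raise.

What the generators do **not** emulate: spatial correlation of real
anastomotic WSS/strain maps, realistic confocal point-spread functions and
depth attenuation, inter-run batch effects in Ct tables, and thixotropy or
temperature drift in rheometry. Passing round-trip tests therefore
demonstrates correctness of the computational chain under its stated
model, not robustness to every artifact of real acquisitions.

## Problem sizes

Defaults keep every computation interactive on one CPU: 0D cycles at 400
steps/cycle converge in ≲ 10 cycles; annulus solves use 801-node Simpson
quadrature inside a Brent iteration; fiber images are 256² with 200
fibers (stability checks 512²/400 fibers); statistical fixtures use the
study's group sizes (n = 4–5) or modest synthetic expansions (e.g. 40 per
group for exclusion-rate checks); seed-sweep properties use 20–100
replicates.
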