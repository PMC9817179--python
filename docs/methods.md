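# Methods

## Four-state fixation kinetics

The model is well-mixed mass action over four species: unfixed in-puncta S1
and out-of-puncta S2, and their irreversibly cross-linked counterparts S3
and S4.  All rates are first order with units s⁻¹:

    dS1/dt = k1·S2 − (k2 + k3)·S1        dS3/dt = k3·S1
    dS2/dt = k2·S1 − (k1 + k4)·S2        dS4/dt = k4·S2

with S1+S2+S3+S4 = 1 mol/L and S3(0) = S4(0) = 0.  The pre-fixation state is
the binding equilibrium: the starting punctate percentage p and the total
exchange rate k1+k2 determine k1 = (p/100)(k1+k2), k2 = (1−p/100)(k1+k2),
equivalently K_eq = k1/k2 = S1_eq/S2_eq.  This coupling matters: the
celebrated zero-artifact identity at k3 = k4 holds exactly *only* when the
initial condition is that equilibrium, because equal added decay then scales
S1 and S2 together.  The API therefore defaults `start_pp` to
100·k1/(k1+k2); callers may still pass an arbitrary start, which is treated
as a general (non-equilibrium) initial condition.

**t = ∞ evaluation.**  The unfixed subsystem x = (S1, S2) is linear,
x' = M x with M = [[−(k2+k3), k1], [k2, −(k1+k4)]].  The time-integrals
I = −M⁻¹x₀ give S3(∞) = k3·I₁ and S4(∞) = k4·I₂ exactly;
det(M) = k1·k3 + k2·k4 + k3·k4.  A vanishing determinant means part of the
unfixed pool has no path to a fixed state; that is a domain error unless the
stranded pool starts empty (e.g. k4 = 0, k1 = 0 but all mass in S1), in
which case the open channel absorbs everything.  With k1 = k2 = 0 and both
channels open, molecules fix in place and the artifact is zero; this is
allowed, not an error.

**Time courses.**  The full system is linear time-invariant, so sampled
trajectories are propagated by the matrix exponential of the 4×4 generator
over the uniform output step.  This is exact to machine precision, conserves
total molarity to ~1e−15 regardless of rate stiffness (ratios of 10³ and
more appear in the sweeps), and removes any solver-tolerance or
end-time-truncation choice.  A stiff ODE integration (LSODA/Radau at
rtol 1e−10) serves as an independent cross-check in the test suite, as does
the closed form at t = 50/min(k3, k4).

**Sweeps.**  Two phase diagrams: (i) vary k3:k4 at constant k3+k4 = 0.2 and
k1+k2 = 1 (relative overall fixation rate 1:5); (ii) vary (k3+k4):(k1+k2)
at constant k3 = 1, k4 = 2.  Default grids: starting punctate percentage 0
to 100 in steps of 2, ratios log-spaced over [10⁻², 10²] with 41 points.
Sign structure: Δ > 0 iff k3 > k4 at interior starts; Δ → 0 at the 0 %/100 %
boundaries and in the fast-fixation limit.

## Puncta quantification

All metrics are defined on z-projections restricted to a 2-D nucleus mask
(hand-drawn in practice; an Otsu helper is included for convenience only).
The maximum projection is normalized so nuclear intensity sums to 1; peak
finding, FWHM refinement and surface roughness use this normalized image,
punctate percentage integrates the sum projection.  All three parameters
are invariant under multiplying the raw stack by a positive gain.

**Maxima / noise tolerance.**  `find_puncta` is a prominence detector with
ImageJ "find maxima" semantics, implemented by union-find over pixels
processed in descending intensity (row-major tie-break, 8-connectivity,
mask-restricted).  A candidate dies at the saddle where its component meets
a higher peak; it is reported when (peak − saddle) strictly exceeds the
noise tolerance.  Components that never meet a higher peak use their own
minimum as reference, so a constant image yields no maxima.  Plateaus
contribute one representative point (rounded centroid).  Maxima touching
the mask edge are kept by default (`exclude_edge` to drop).  The tests pin
this detector against an independent threshold-descent oracle, exactly, on
images with plateaus and irregular masks.  The noise tolerance has no
universal value; it is a required parameter, constrained identical for a
live/fixed pair, and can be given in normalized or raw intensity units.

**FWHM.**  36 diameter slices at 5° increments through the preliminary
center, sampled by bilinear interpolation at 0.25 px steps up to ±30 px.
Each profile's local baseline is its minimum; crossings of
baseline + amplitude/2 are located by linear interpolation from the slice's
peak outward.  The punctum's FWHM is the maximum over slices (the slice
through the true center), and the crossing midpoint of that slice refines
the center.  Slices with no measurable amplitude (relative amplitude below
1e−9, e.g. flat profiles) are skipped; a punctum with no resolvable slice is
flagged and excluded from disk-based metrics with a warning.

**Punctate percentage.**  Disks of diameter FWHM centered at refined
centers, clipped to the mask, overlaps counted once; the value is 100× the
in-disk share of the sum-projection nuclear intensity.  For an ideal 2-D
Gaussian punctum the FWHM disk contains exactly half the energy
(1 − e^(−ln 2) = 1/2), which the tests use as an analytic anchor.

**Percent change.**  100·(fixed − live)/live per parameter; a zero live
value flags the percent change invalid (NaN) with the absolute change still
reported.  Population (divide-by-N) standard deviation is used for
roughness; percent change is insensitive to the convention.

## SPT residence times

Dwell = track span (last − first + 1 frames) × 0.5 s frame interval;
single-localization tracks are dropped.  Trajectories are classified by F
computed against the temporally nearest puncta mask (masks every ~10 s);
only in-puncta tracks (F > 0.5) enter the survival analysis, ambiguous
tracks (0.05 ≤ F ≤ 0.5) are retained but excluded.

The empirical survival curve P(t) (fraction of dwells ≥ t on the observed
dwell grid) is fitted by trust-region constrained least squares to
A·e^(−λ_ns t) + (1−A)·e^(−λ_s t), with 0 ≤ A ≤ 1, rates positive, five
multi-starts over log-spaced fast rates, and component identity enforced by
λ_ns ≥ λ_s.  **Time origin:** the model clock starts at the smallest
observed dwell.  Dwells are quantized *up* to whole frames, so the
empirical survival at grid point k·Δ equals the continuous mixture's
survival at (k−1)·Δ; anchoring the origin one frame in makes the fit
asymptotically unbiased under this quantization.  `predict(0)` is exactly 1
by model form.  If the amplitude pins at a bound or the two rates coincide
(within 5 %), only one exponential is identified: the fit collapses to a
single-exponential refit reported as the slow component with
`boundary_amplitude=True`.

Photobleaching shortens apparent residence times; under rate-level
composition (observed rate = true rate + bleach rate) the correction
τ_corrected = 1/(1/τ_s − 1/τ_H2B) is exact, with τ_H2B the specific time of
chromatin-immobile H2B imaged under identical illumination,
session-matched.  τ_s ≥ τ_H2B is a domain error (the apparent time cannot
exceed the bleach-limited ceiling).  Only the specific (slow) component is
reported downstream; per-cell corrected times are summarized as
mean ± SEM with a rank-sum comparison between two conditions.

Fits are uncensored; dwell observation windows (e.g. 1000 s movies) are
modeled in the generator but not in the likelihood — a limitation that is
negligible when the window exceeds ~20 observed slow time constants, as in
all configurations shipped here.

## Synthetic data

Generators are pure functions of (spec, seed) — same inputs, bit-identical
outputs — and attach complete ground truth.

* **Nucleus stacks**: elliptical nucleus (default semi-axes 80×70 px in a
  5×192×192 stack) at uniform background 10, with n 3-D Gaussian puncta
  (lateral σ 2 px, axial σ twice that, confocal-like; amplitude 50) placed
  by rejection sampling at ≥ 6σ separation so every planted punctum is
  resolvable, plus additive Gaussian read noise (σ 1), clipped at 0.
  Amplitude:noise of 50 reflects clearly phase-separating overexpressed
  proteins.  Poisson shot noise, PSF tails and intranuclear texture are not
  modeled: passing tests certify the estimators on their stated model, not
  performance on dim or textured real nuclei.
* **Live/fixed pairs**: the fixed image rescales planted punctum count
  and/or amplitude; expected change signs are recorded where determinate.
* **Dwell times**: two-component exponential mixture (nonspecific fraction
  A, times τ_ns < τ_s) with bleaching added at the rate level
  (1/τ + 1/τ_bleach), rounded up to 0.5 s frames, optionally capped at the
  movie length.
* **Trajectories**: tracks with F constructed to 0.8 / 0.0 / 0.25 for
  in/out/ambiguous labels, variable lengths (4..n_frames) for
  non-degenerate dwell sets.

## Statistics

Wilcoxon signed-rank (paired per-cell changes; zeros dropped; exact null up
to n = 25, continuity-corrected normal approximation above) and Wilcoxon
rank-sum / Mann-Whitney U (independent groups; exact for small samples via
scipy's auto rule).  Both are pinned against brute-force enumeration of the
null in the tests, and the signed-rank test's type-I error is verified near
the nominal 5 %.

## Problem sizes

Default study sizes keep everything desk-scale: 41×51 sweep grids, 5×192×192
synthetic stacks with 12 puncta, 5000 dwells per survival fit, 100-point
randomized grids for the kinetic identities.  These match the regimes the
analyses are designed for (tens of puncta per nucleus, thousands of pooled
trajectories per condition).
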