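# Methods

## Kinetic models and fitting

Tissue concentration is modelled by the nested family

* order 1: `Ct = vp·Cp`
* order 2: `Ct = vp·Cp + Ktrans·∫ Cp dτ` (Patlak limit)
* order 3: `Ct = vp·Cp + Ktrans·(Cp ⊛ e^(−kep t))` (extended Tofts)

on the plasma curve `Cp(t)` sampled at the dynamic frame rate. Time is
converted from seconds to minutes so `Ktrans` and `kep` are reported in
min⁻¹ and `vp`, `ve = Ktrans/kep` are unitless fractions. The kinetic
integrals are anchored at the bolus-arrival sample, detected as the first
frame where `Cp` exceeds its baseline mean by five baseline SDs (the
injection frame is part of the protocol; the arrival of contrast in the
sampled curve is what fixes the time origin). The running integral uses the
cumulative trapezoid on the 4 s grid; the backflux convolution uses the
exact piecewise-linear kernel, whose `kep → 0` limit reproduces the
trapezoid so the order-3 → order-2 nesting is exact to rounding.

Orders 1–2 are linear least squares. Order 3 is separable: for fixed `kep`
the problem is linear in `(vp, Ktrans)`, so the fit profiles the linear
pair over a scalar search in `kep` — a coarse log-spaced grid (40 points up
to 10 min⁻¹, including the Patlak point `kep = 0`) brackets the optimum and
40 golden-section iterations refine it. On noiseless model-generated data
this recovers parameters to better than 1 part in 10⁴ across the tested
grid.

Two kinds of output coexist per voxel:

* **Residuals for testing.** The recorded SSE₁ ≥ SSE₂ ≥ SSE₃ come from the
  *unconstrained* nested least-squares fits. This is deliberate: the
  sequential F-tests that assign model orders rest on classical nested-LS
  distribution theory, and constraining coefficients to be nonnegative
  truncates the null distribution and makes the tests conservative (the
  measured type-I rate of the 1→2 step then falls to roughly half the
  nominal level). With unconstrained residuals the 1→2 step is calibrated:
  4.9% rejections at α = 0.05 over 10⁴ null voxels.
* **Parameters for maps.** Reported estimates are projected to the physical
  domain (nonnegative `vp`, `Ktrans`; `kep ≥ 0` is structural to the
  search). The projection only binds on voxels whose signal is
  noise-dominated, which the selection stage assigns to low orders anyway.

The 2→3 step tests a parameter (`kep`) pinned to a boundary under the
null, so its null distribution is a mixture and the step is conservative at
nominal α; selection therefore errs toward parsimony, which is the safe
direction for `ve` maps. Steps accept at `p ≤ α` so the `α = 1` limit
promotes every fittable voxel.

## Model selection

Sequential F-tests 1→2→3 with `p₁, p₂, p₃ = 1, 2, 3` parameters and `n` =
number of post-arrival frames; selection stops at the first non-significant
step; default α = 0.05 per step with no across-voxel multiplicity
correction (map-making convention, configurable). Voxels whose baseline
SNR falls below 5 (estimated from the pre-bolus frames) are classed as
background (order 0) before any fitting. `ve` is emitted only on order-3
voxels, `Ktrans` from order 2, `vp` from order 1 — each parameter reported
only where it is identifiable.

## Signal chain

**Look-Locker T1.** Three-parameter magnitude model
`|S(TI)| = |A − B·e^(−TI/T1*)|` with polarity restored by a sign-flip
search at the two candidate zero crossings around the signal minimum. The
fit is separable (linear in `A, B` for fixed `T1*`): a coarse bracket plus
vectorized golden-section search, then a few safeguarded Gauss–Newton
steps on the full model (golden section alone localizes `T1*` only to
√ε·scale, and the residual invariant demands better). The readout
correction `T1 = T1*(B/A − 1)` is exact for the generator's driven-
equilibrium forward model. Non-converged voxels (zero series, `B ≤ A`) are
flagged and excluded downstream rather than raising.

**Dual-echo split.** `R2* = ln(S1/S2)/(TE2 − TE1)`, `S0 = S1·e^(TE1·R2*)`.
A second echo slightly above the first is an ordinary noise excursion and
the implied small negative `R2*` is kept: truncating at zero would bias the
TE→0 amplitude in a signal-level-dependent way and forge spurious
enhancement (measured as a doubled false-leakage rate before this choice
was made). Inversions beyond 4√2 noise SDs are clamped with a warning;
more than 50% inverted samples means the echoes are systematically
swapped, and the split refuses.

**Concentration.** The voxel scale `M0` is fixed from the baseline mean
(frames 2 to bolus−1; frame 1 skipped for steady-state settling) together
with the pre-contrast T1; each frame is then inverted in closed form
through the spoiled gradient-echo equation for `R1(t)`, and
`Ct = (R1 − R1,pre)/r1`. Out-of-domain frames (signal at or above the
theoretical ceiling `M0·sin α`) are flagged and linearly interpolated from
neighbours; voxels with more than 10% flagged frames are excluded. The
post-contrast Look-Locker scan is generated and stored but the default
pipeline does not use it for recalibration.

## Synthetic cohort

The generator emulates a two-session (24 h apart) small-animal study with
treatment before the second session at 2, 4, 8, 12 or 24 h; default group
sizes 7, 6, 6, 6, 6 (N = 31). Geometry: a 32×32×3 grid at 1×1×2 mm (32 mm
field of view), a circular brain slab, and a circular tumor (default
radius 4 mm) in the lateral half with concentric zones — periphery
(order 2: leakage without measurable backflux), body (order 3), and a core
distinguished by reduced plasma volume (necrotic center). Zone defaults
(body `vp` 0.025, `Ktrans` 0.030 min⁻¹, `kep` 0.30 min⁻¹, i.e. `ve` 0.10;
core `vp` 0.010) are realistic for an aggressive orthotopic glioma at
7 T and are placed at least three shift-SDs above the physical floor so the
treatment-shift law below is realized without truncation — a constraint
the shift variances impose on any valid parameterization. Per-animal
biological variability multiplies zone kinetics by ~5% lognormal-like
factors (same baseline for both sessions).

The treatment effect is a per-animal shift of `(vp, Ktrans, ve)` applied
uniformly to the order-3 tumor voxels of the retest map, drawn from
group-specific Gaussians. The early (2 & 4 h) and late (12 & 24 h) group
laws use the published pooled test–retest difference summaries (mean ± SD:
`Ktrans` +0.0050 ± 0.0050 and −0.0039 ± 0.0064 min⁻¹; `ve` +0.0005 ±
0.0166 and −0.0164 ± 0.0251; `vp` +0.0016 ± 0.0052 and −0.0006 ± 0.0030);
the 8 h group is centred on zero with the midpoint SD, matching the
reported "pivot" behaviour. Shifts that would leave the physical domain
are clipped with a warning (rare by construction, see above).

The plasma curve is an idealized biexponential bolus (defaults: 3.0 mM at
1.5 min⁻¹ plus 1.5 mM at 0.05 min⁻¹, i.e. a 4.5 mM peak at the injection
frame) delivered already as plasma concentration — the generator's
hematocrit (0.45) is applied nowhere downstream. No measured input
function exists for this design; user-supplied curves are accepted as
two-column CSV. Signal physics: steady-state spoiled gradient echo with
`R1(t) = R1,pre + r1·Ct(t)` (relaxivity default 3.8 s⁻¹mM⁻¹ at 7 T), a
*static* `R2*` (default 40 s⁻¹, i.e. T2* = 25 ms), flip angle default 25°
(the acquisition's flip angle is not part of the published protocol;
configurable), echo decay `e^(−TE·R2*)`, driven-equilibrium Look-Locker
trains with a 12° readout, and a two-point DWI pair from a per-zone ADC
field. Noise is Rician on every magnitude sample, parameterized by the
baseline SNR of brain voxels (default 30); `sd = 0` gives bit-exact
noiseless output. All randomness flows from a single seed through
`SeedSequence` spawning, so identical seed + design is bit-identical.

What the generator does *not* emulate: real anatomy, motion and inflow
artifacts, B1 inhomogeneity, partial-volume mixtures at zone borders,
spatially correlated noise, and within-zone parameter texture. Passing
tests therefore demonstrate correctness of the estimators and statistics
under the stated physics, not robustness to those confounds.

## Cohort statistics

Each animal is summarized by the mean (median selectable) of each
parameter over the intersection of its test and retest order-3 masks
(test-only or retest-only masks selectable), restricted to the tumor
footprint — the analysis ROI that an operator would draw on the
localization images, which for virtual animals is the generator's tumor
extent. Restricting to the ROI matters: isolated false order-3 calls
scattered over the much larger normal-brain area would otherwise dilute
per-animal means. Differences are retest − test, in absolute units and in
percent of the test value (flagged undefined at a zero test summary).
Group-table comparisons use absolute mode — the published difference
magnitudes (~0.005 min⁻¹) are on the parameter scale, not percentages —
while distribution plots use percent mode.

Statistics: two-sided paired t-test per treatment-time group (equivalent
one-sample t on the differences; zero-variance groups flagged instead of
given a p-value); one-way ANOVA across the five groups from explicit sums
of squares (verified against an OLS contrast as an independent route); and
a planned contrast of pooled early vs pooled late animals with
size-weighted coefficients — so the estimate equals the difference of the
two pooled-group means — tested against the ANOVA MSE with N − k degrees
of freedom. No multiplicity adjustment across the three parameters.
Boxplot exports use quartiles with 1.5×IQR whiskers and explicit outlier
lists.

## Problem sizes and numerical choices

Validation workloads are desk-scale by design: 32×32×3 grids (~1800 brain
voxels per session), 150-frame series, 20 replicate cohorts in the
acceptance script (~7 min), 10⁴-voxel calibration runs. Tolerances: the
noiseless end-to-end round trip recovers `(vp, Ktrans, kep)` to < 0.1%
(observed ~10⁻⁷); golden-section budgets (40 iterations) put optimizer
error far below noise floors; ties in the nesting (`SSE₃ = SSE₂` when the
backflux search gains nothing) resolve to the Patlak solution with
`kep = 0`, never to a spurious positive backflux.

## Known limitations

* The ve test–retest differences show a small positive interaction bias
  (~+0.002 in the early group at SNR 30) from conditioning on Model-3
  selection in both sessions; it is an order of magnitude below the
  group-difference tolerances but visible in large replicate averages.
* The 2→3 selection step is conservative (boundary null), so Model-3
  regions are slightly under-called at low contrast-to-noise.
* The per-voxel covariances reported for order 3 treat `kep` as fixed at
  its estimate (linear-pair covariance only).
* Percent-mode differences inherit the instability of small test-session
  denominators; absolute mode is the default for group tables.
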