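# Methods

## Scope and model

`adrisk` models preclinical Alzheimer's risk in cross-sectional cohorts
carrying four numeric biomarkers per individual — CSF Aβ42, amyloid PET,
CSF Tau, and a combined MRI/FDG-PET structural-metabolic composite — plus
age.  Three components make up the framework:

1. **Trajectory model.** Each biomarker's expected level at age `x` is a
   logistic curve `S(x) = L / (1 + exp(k(x − x0)))`.  The curve is kept in
   this exact form, which is *decreasing* in `x` for `k > 0`; rising
   trajectories therefore take `k < 0` rather than a rewritten formula.
   `x` is interpreted as age when simulating; `x0` is then the age of the
   curve's midpoint and is configurable (an alternative reading of `x0` as
   the biomarker-column mean is supported by configuration, not
   hard-coded, since nothing else in the model distinguishes the two).
   The closed-form derivative `S′(x) = −k·S·(1 − S/L)` locates the steep
   midlife portion of each trajectory.

2. **CI score.** Cognitive impairment at age `A` is
   `CI(A) = α·e^{βA} + Σᵢ wᵢ·kᵢ·e^{−mᵢA}`.  All four biomarker terms are
   written uniformly with rate `−mᵢ`; rising markers use `mᵢ < 0`.  The
   protective direction of Aβ42 is carried by `w₁ < 0`.  The observation
   form substitutes an individual's measured values for the modeled terms
   and is linear in each measurement at fixed age; the two forms agree
   exactly when measurements sit on their modeled trajectories (a tested
   invariant).

3. **Risk zones.** A registry of age bands supplies cut-points γ and δ;
   Safe is `CI ≤ γ` (boundary inclusive), Mild Risk `γ < CI ≤ δ`, Unsafe
   `CI > δ`.  Bands use the half-open `(lower, upper]` convention — the
   only worked boundary case in the reference panel (age 40, CI 3.37,
   Mild Risk) is consistent only with age 40 belonging to the 30–40 band,
   which fixes the convention.  The default registry is (30,40]:(3,6),
   (40,50]:(4,7), (50,60]:(5,8), (60,70]:(6,9).  Each band also carries
   three *display* CI ranges used for reporting and plausibility warnings
   only; a CI below the displayed Safe floor still classifies Safe, with
   a logged warning, because the defining inequalities know only γ and δ.
   An optional four-zone relabeling splits Unsafe at the band's displayed
   upper edge into High Risk vs MCI; the three-zone system is the default
   because only two cut-points are defined.

## Threshold templates

Independent of the CI bands, per-age-group templates flag each biomarker
as Normal / Low Risk / High Risk.  Templates are keyed by their own
`(lower, upper]` age intervals (30–40, 40–50, 55–65); the 55–65 group
matches no CI band, and the two groupings are deliberately *not* forced
into alignment.  Aβ42's ranges run opposite to the other markers, encoded
by a per-biomarker direction flag (`lower-is-risk` for Aβ42).  Range
boundaries fall into the next category along the risk direction:
`[lo, hi)` for higher-is-risk markers, `(lo, hi]` for Aβ42.  Values beyond
the tabulated extremes flag High Risk on the risky side and Out of Range
on the safe side.  A second reference block carries published clinical
cut-offs on the pg/mL / Centiloid scale (Aβ42 480/800 pg/mL, age-specific
Tau limits, Centiloid 0–100); it is kept strictly separate from the
template scale because no conversion between the two unit systems is
defined, and cohort tables are stored verbatim in whichever system they
arrive.

## Synthetic cohort generator

The generator emulates the kind of pooled cross-sectional data the
screening pipeline expects: one logistic trajectory per biomarker,
additive Gaussian measurement noise floored at zero, and a negative
coupling `τ·(Aβ42 − its curve)` added to Tau (default τ = −0.5) so Aβ42
and Tau residuals are negatively correlated, as in amyloid-driven
neurodegeneration.  Defaults (all illustrative, on the template threshold
scale): Aβ42 (L=22, k=0.08, x0=60), amyloid PET (20, −0.08, 50), CSF Tau
(16, −0.08, 50), FDG-PET (14, −0.08, 55); noise sd = 5 % of each plateau.
These were chosen once so that mid-band curve values sit inside the
Normal template ranges at ages 30–40 and drift into Low-Risk ranges by
60, and the default CI parameters (α=0.5, β=0.04, w = −0.05/0.1/0.1/0.1)
keep the modeled CI inside the displayed band envelope (0–14) over ages
30–70, crossing γ near age 40 and δ in the mid-60s.

The default screening pool is 5 instances at each integer age 31–60
(150 instances).  The grid starts at 31 because age 30 sits on the open
lower edge of the lowest band and is unclassifiable under the
`(lower, upper]` convention.  All randomness derives from one root seed
via per-biomarker child streams in fixed canonical order, so output is
bit-reproducible and independent of mapping iteration order.

What the generator does *not* emulate: longitudinal within-person
dynamics, cohort effects, assay/scanner batch offsets, covariance beyond
the single Aβ42–Tau coupling, and non-logistic kinetics.  Tests passing
on generated data therefore validate the pipeline's mechanics and the
model's internal consistency, not clinical accuracy on real cohorts.

## Cleaning and imputation

Age is the instance identifier.  Aggregation rounds ages to the nearest
year, collapses ties to the arithmetic mean per column, and sorts; it is
idempotent and mean-preserving per age group.  Missing whole ages on the
integer grid are filled from the trajectory model (optionally with
noise); missing single cells are filled from the same model,
deterministically — one mechanism for both gap kinds.  Filled rows carry
a `synthetic` flag and a provenance note.  Non-strict reading drops rows
with invalid ages or negative/non-finite values (logged) and keeps empty
cells as NaN for the imputation stage; strict reading raises on any
defect.  CSVs are written with 9 significant digits, enough to round-trip
the precision of typical source tables.

## Calibration

`calibrate_ci_params` fits (α, w₁..w₄) by ridge-penalized least squares
with β profiled over a fixed grid (0–0.1, step 0.001), minimizing
`Σ(CI_obs − target)² + ridge·‖θ_s‖²`.  Columns are scaled to unit RMS
before penalization so pg/mL-scale and unit-scale biomarkers are
penalized evenly; coefficients are reported on the original scale.  The
default ridge 1e−3 keeps the fit well-posed even for a single record
(eight records cannot identify ten free parameters).  A negative fitted α
violates the α ≥ 0 constraint and triggers a deterministic refit with the
age column dropped.  Each biomarker's (kᵢ, mᵢ) is recovered from its own
age trajectory by the log-linear exponential fit, falling back to a
constant at the cohort mean when that fit is undefined (non-positive
values or a single age).  Calibrated on the worked-example panel, the
fitted scores reproduce all eight reference zone labels; the CI values
themselves are under-determined and are not claimed to be recovered.

## Numerical choices

- Sigmoid exponent clipped at ±709; beyond that the asymptote (0 or L) is
  returned exactly rather than overflowing.
- Simulated values are floored at 0 (biomarker levels are non-negative).
- Bin standard deviations use the population form (ddof = 0) so a
  single-record bin reports 0 rather than NaN.
- `intervention_window` scans at the requested step and refines each zone
  crossing by bisection to 1e−6 years; the bisection assumes one crossing
  per bracketing step, so callers probing deliberately oscillatory
  parameter sets should reduce the step.  When the Unsafe zone is never
  reached the window's right end is censored at the scanned range.
- `safe_biomarker_bounds` solves the Safe inequality in closed form; the
  returned boundary value itself sits at CI = γ up to rounding, i.e. on
  the Safe side by the boundary convention but within one ulp of it.
- Duplicate-age rounding uses IEEE round-half-to-even via `numpy.rint`;
  exact .5 ages are rare and the choice is documented rather than
  load-bearing.

## Known limitations

Default parameter sets are illustrative and visibly non-canonical; any
scientific use requires explicit calibrated configuration.  The unit
systems of the template thresholds and the pg/mL clinical references are
not reconciled.  The framework is cross-sectional: it cannot separate
ageing from cohort effects, and the intervention window is a property of
the modeled mean trajectory, not a per-individual prediction.
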