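# Methods

This note documents the models implemented in `varivent`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know about.

## Ventilation patterns

A PVV pattern is a cyclic replay of a pre-recorded breathing reference with
a single global tidal-volume rescaling so the emitted pattern's mean VT
equals the target (8 mL/kg by default, with PEEP 6 cmH₂O).  Because the
rescaling is one multiplicative constant, the coefficient of variation of
VT and all timing statistics are inherited from the reference exactly; this
is asserted, not approximated.  PCV delivers identical breaths with cycle
time 60/RR and an even inspiratory/expiratory split by default.

The synthetic breathing reference draws VT and respiratory rate from
truncated Gaussians (bounds 0.5×–1.5× the mean), which prevents
non-physical breaths while leaving the first two moments essentially
unchanged for the CVs of interest (at CV 0.15 the truncation points sit at
±3.3 SD).  The reference CV defaults to 0.15; recordings of spontaneously
breathing rabbit pups are not published in a form that pins this number
down, so it is a configuration parameter, not a claim.

### Protocol rules

The FiO₂ titration is a four-tier piecewise-constant map on PaO₂/FiO₂ with
half-open bins, upper edges belonging to the lower-FiO₂ tier:
(250, ∞) → 0.4, (200, 250] → 0.6, (100, 200] → 0.8, (0, 100] → 0.9.  The
0.9 tier is keyed on the ratio (≤ 100 mmHg) for consistency with the other
tiers; reading it on absolute PaO₂ instead is a one-line change where the
rule is applied, and the tier table is the single source of truth.
Berlin severity uses the standard ratio bins (mild (200, 300], moderate
(100, 200], severe ≤ 100).  The ARDS-induction stopping rule returns the
first index with PaO₂/FiO₂ in [250, 300] inclusive.

The normocapnia controller is deliberately minimal: inside the 5.5–6.0%
end-tidal CO₂ band the rate is unchanged; outside, a proportional step
`rr + gain·(etCO₂ − 5.75)` (default gain 8 breaths/min per %CO₂) clamped
to 10–150 breaths/min.  Clinically the adjustment is a judgment call; only
the target band is well defined, so the controller's shape is a design
choice, not physiology.

R-peaks for heart rate are detected by thresholding the ECG at
mean + 2 SD with a 200 ms refractory period; HR is 60 over the median
inter-peak interval, which is robust to isolated missed beats.  MAP is the
time average of the arterial-pressure waveform.

## Forced-oscillation mechanics

Input impedance comes from the wave-tube relation
`Z_load = Z₀·sinh(γL)/(P₁/P₂ − cosh(γL))`; frequencies where the
denominator falls below a tolerance (load ≈ infinite, e.g. a closed distal
end) are excluded with a warning rather than propagated as infinities.

The constant-phase model `Zrs = Raw + iωIaw + (G − iH)/ω^α` with
`α = (2/π)·arctan(H/G)` is fitted by trust-region-reflective least squares
on the stacked real and imaginary residuals.  Key choices:

* **Units.**  ω = 2πf inside the model; all interfaces carry Hz.  A
  mismatch here silently rescales G and H, so the convention is pinned by
  tests against an independently coded evaluator.
* **Weighting.**  Residuals are divided by |Z_meas| (relative error), which
  keeps the elastance-dominated low frequencies and inertance-dominated
  high frequencies comparable; uniform weighting is selectable.
* **Bounds, not transforms.**  Non-negativity of (Raw, Iaw, G, H) is
  enforced by box bounds so exact zeros are representable (a pure resistor
  fits with G = H = Iaw = 0, and α is then taken as 0 with a zero tissue
  term by convention).
* **Starting point.**  Raw from the real-part floor, H from the
  low-frequency reactance magnitude, G = H/3 (hysteresivity ≈ 0.33, typical
  for lung tissue), Iaw from the high-frequency reactance slope.  The fit
  is deterministic given the spectrum and starting point.
* **Frequency band.**  Default 16 pseudo-logarithmic points over 0.5–20 Hz,
  a standard small-animal oscillometry band; configurable.

Fitted parameters describe the **total respiratory system**; the chest-wall
contribution (tens of percent for the tissue parameters) is not separated,
so tissue-parameter changes understate the purely pulmonary changes.

Relative change trajectories are `100·(x_t − x_T0)/x_T0` against the
post-induction baseline T0.

## Imaging quantification

CT voxels inside the lung mask are labeled well aerated [−1000, −500),
poorly aerated [−500, −100) or non-aerated [−100, +100] HU — the standard
quantitative-CT aeration cut-points; bins are left-closed.  Values outside
[−1000, +100] (cone-beam scatter artefacts) are clipped to the nearest
edge before labeling and the clip count is reported.  Tissue fraction is
the linear two-point mixture between −1000 HU (pure gas) and 0 HU (pure
tissue).

Uptake is expressed as SUV = activity/(dose/weight) (tissue density
1 g/mL) and divided by the voxel tissue fraction, so metabolic signal is
not confounded by how much parenchyma each voxel holds.  Voxels with
tissue fraction below 0.05 are excluded from normalization — the divisor
is otherwise unbounded — and exclusion counts are reported so analyses
remain auditable.  PET and SPECT use the identical normalization map.

The ventral/dorsal split plane passes through the lung-mask centroid
perpendicular to the gravity axis (not the image midline), making it
robust to where the lung sits in the field of view; halves are balanced to
within one slice's voxels.  Regional summaries report per-region mean
normalized uptake, voxel count, volume and mean HU (MPV); empty regions are
reported as undefined (NaN), never zero, and count-weighted region means
reconstruct the whole-lung mean to 1e-9 by construction.

No registration, reconstruction, scatter or partial-volume correction is
performed; inputs are assumed co-registered, which is true for generated
phantoms and is the package's stated scope.

## Synthetic generators

The phantom assigns mask voxels (an ellipsoid, ~52% of the bounding box) to
aeration zones in ventral-to-dorsal order — atelectasis accumulates in the
dependent lung — with exact zone voxel counts up to rounding.  CT voxels
get their zone's HU mean plus Gaussian jitter (SD 30 HU) clipped strictly
inside the zone's bin, so segmentation recovers the programmed composition
exactly; this is a deliberate idealization that separates "does the
quantification chain conserve what was programmed" from segmentation
robustness, which real cone-beam data would stress.  PET/SPECT activity is
constructed backwards from target normalized uptake (activity =
u·f_tissue·dose/weight, with 5% mean-preserving jitter), so the SUV →
normalization → regional-summary round trip is an end-to-end conservation
test.  Default zone composition: (0.85, 0.12, 0.03) for healthy lungs,
(0.55, 0.25, 0.20) for ARDS; zone uptake pattern 2 : 1 : 0.5
(well : poor : non), rescaled per animal to hit its whole-lung target.

Cohort tables draw each (animal, timepoint, variable) as
mean + animal intercept + residual, the same structure the mixed model
fits.  Positive-skewed variables (e.g. lactate) are drawn moment-matched
lognormal, with the animal effect as a shared log-scale component, so
programmed means are preserved and values stay positive.  Printed
mean ± CI-half-width values are converted to SDs via
`SD = hw·√n / t(0.975, n−1)` when used as programmed dispersions.

What the generators do **not** emulate: recruitment/derecruitment physics,
gas-exchange feedback (blood gases are programmed trajectories, not
predictions), imaging physics (scatter, motion, partial volume), or any
mechanistic link between ventilation mode and outcome — group effects are
descriptive levels taken from the published summary statistics.  Passing
tests therefore demonstrate that the estimation chains are unbiased and
conservative on data with the declared structure, not that the biology is
modeled.

## Statistics

Each variable passes a Shapiro–Wilk gate (α = 0.05); on failure it is
natural-log-transformed.  When the transform is infeasible (non-positive
values, e.g. percent changes), the library raises a dedicated error and the
pipeline analyzes the variable untransformed with a logged warning.  The
gate is applied to the variable's pooled values; a residual-based variant
is a straightforward extension.

The repeated-measures ANOVA is a REML linear mixed-effects model
(statsmodels `MixedLM`) with group × time fixed effects (both categorical)
and a random intercept per animal.  Two deliberate choices:

* **Sum-to-zero contrasts.**  Each model term then represents a marginal
  (time-averaged) effect, keeping the between-animal and within-animal
  error strata separate in the Wald statistics.
* **Between-within (containment) denominator degrees of freedom** for the
  per-effect F tests: `n_animals − g` for the between-subject group effect
  and `(n_animals − g)(t − 1)` for within-subject effects.  These are the
  exact classical ANOVA df for the balanced compound-symmetric designs the
  generator emits, and a standard finite-sample approximation otherwise;
  simulated null rejection rates sit at the nominal 5% (checked at 500
  replicates in the test suite).  A Satterthwaite/Kenward–Roger style
  per-contrast df was considered and rejected as substantially more
  machinery for no gain on this design class.

Numerical robustness: the REML optimizer falls back from L-BFGS to
derivative-free methods when the profiled likelihood is near-singular
(common under boundary variance estimates on null data), and the exactly
noiseless limit short-circuits to OLS on the same design with zero
variance components — cell means are then reproduced exactly and effects
get p ∈ {0, 1}.

Post-hocs follow the study convention: Dunnett for many-to-one comparisons
against the reference timepoint (T0) within groups, Holm–Šidák for
between-group families.  The Dunnett adjustment maps raw two-sided t
p-values to |t| at the family's df and evaluates
P(max_j |T_j| ≥ |t|) under the equicorrelated multivariate t (ρ = 0.5 for
a shared reference with equal n) by seeded Monte-Carlo, 50,000 draws —
accuracy ≈ 0.005, cross-checked against an independent sample-based
implementation in the tests.  Holm–Šidák uses the closed-form step-down
`p̃_(i) = max_{j≤i} 1 − (1 − p_(j))^(m−j+1)`.

Summaries are mean ± half-width of the 95% CI,
`hw = t(0.975, n−1)·sd/√n`.

## Pipeline and problem sizes

`run_study` chains the stages from a single seeded config and writes tidy
CSVs plus a manifest (seed, config hash, package versions, SHA-256 of every
output); identical configs produce byte-identical outputs.  Default sizes
are the published cohort (7/7/12/10 animals, 7 timepoints): ~250
constant-phase fits and ~36 phantoms at 32³ voxels, a few seconds on one
CPU.  The recovery computations in `scripts/acceptance.py` use 200 seeds
for the mechanics chain and 50 seeds of 7 phantoms for the imaging chain —
enough to push the Monte-Carlo error of the seed-averaged group means well
below the programmed dispersions.  Unit tests that average over seeds use
tolerances of three Monte-Carlo standard errors of the statistic under
test, computed a priori from the programmed SDs.

## Known limitations

* Blood-gas and mechanics effect profiles are descriptive; nothing couples
  ventilation settings to outcomes mechanistically.
* Phantom segmentation is exact by construction; threshold sensitivity and
  artefact robustness on real cone-beam CT are untested here (the HU
  cut-points and the tissue-fraction calibration are config-exposed for
  exactly that reason).
* The containment df are exact only under balance; heavily unbalanced or
  missing-data designs would warrant Satterthwaite df.
* The wave-tube entry point assumes calibrated Z₀ and γ; transducer and
  tube acoustics are out of scope.
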