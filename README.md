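# varivent

Quantitative analysis pipeline for studies of **physiologically variable
ventilation (PVV)** versus conventional **pressure-controlled ventilation
(PCV)** in small-animal models of pediatric ARDS — exercised entirely on
synthetic data with explicitly programmed statistical structure.

The package is aimed at respiratory physiologists and methodologists who
want a reproducible, testable implementation of the measurement and analysis
chain used in such studies:

* **Ventilation patterns and protocol rules** — PVV breath sequences that
  replay a recorded physiological breathing pattern (rescaled to a target
  mean tidal volume, breath-to-breath variability preserved exactly),
  monotonous PCV sequences, the four-tier FiO₂ titration on PaO₂/FiO₂, the
  Berlin ARDS severity grades, the ARDS-induction stopping rule (halt when
  PaO₂/FiO₂ first enters 250–300 mmHg), driving pressure, and MAP/HR
  extraction from recorded waveforms.
* **Forced-oscillation lung mechanics** — respiratory input impedance via
  the wave-tube transmission-line relation
  `Z_load = Z₀·sinh(γL) / (P₁/P₂ − cosh(γL))`, and constant-phase model
  fitting

  ```
  Zrs(ω) = Raw + iωIaw + (G − iH)/ω^α,   α = (2/π)·arctan(H/G),  ω = 2πf
  ```

  estimating airway resistance Raw, inertance Iaw, tissue damping G and
  tissue elastance H by bounded complex nonlinear least squares.
* **Quantitative CT / PET / SPECT** — aeration compartments from HU bins
  (well [−1000, −500), poorly [−500, −100), non-aerated [−100, +100]),
  gas/tissue fractions from the linear −1000/0 HU mixture, standardized
  uptake values SUV = activity/(dose/weight), tissue-fraction-normalized
  uptake, ventral/dorsal splitting through the lung centroid, and regional
  aggregation.
* **Longitudinal statistics** — Shapiro–Wilk normality gate with log
  fallback, repeated-measures ANOVA via REML linear mixed-effects models
  (group × time fixed effects, random intercept per animal), Dunnett
  (vs a reference timepoint) and Holm–Šidák post-hoc adjustments, and
  mean ± 95% CI-half-width summaries.
* **Synthetic data generators** for all of the above: breathing references,
  noisy impedance spectra, co-registered lung phantoms with programmed
  aeration composition and zone uptake, and longitudinal cohorts with
  animal-level random intercepts.

## Worked example

```python
import numpy as np
from varivent import (CPMParameters, synth_impedance, cpm_fit,
                      synth_lung_phantom, segment_aeration, compute_suv,
                      normalize_uptake, regional_summary,
                      titrate_fio2, classify_berlin)

# --- forced oscillation: synthesize a noisy spectrum and fit it back
freqs = np.geomspace(0.5, 20, 16)                      # Hz
truth = CPMParameters(raw=20.0, iaw=0.1, g=400.0, h=2000.0)
spectrum = synth_impedance(truth, freqs, noise_sd=0.05, seed=1)
fitted, residual = cpm_fit(spectrum)
print(f"Raw = {fitted.raw:.1f} cmH2O.s/L, G = {fitted.g:.0f}, H = {fitted.h:.0f} cmH2O/L")
print(f"alpha = {fitted.alpha:.3f}, eta = {fitted.eta:.3f}, residual = {residual:.4f}")

# --- imaging: ARDS-like phantom, segmentation and normalized uptake
vols = synth_lung_phantom(shape=(32, 32, 32), zone_fractions=(0.55, 0.25, 0.20),
                          zone_uptake_means=(2.4, 1.2, 0.6), seed=7)
aeration = segment_aeration(vols.ct, vols.mask)
suv = compute_suv(vols.pet, injected_dose=37_000.0, body_weight=670.0)
normalized, _ = normalize_uptake(suv, vols.ct, vols.mask)
summary = regional_summary(vols, aeration, normalized, normalized)
print(summary[summary.modality == "pet"].set_index("region")
      [["mean", "count", "volume_ml"]].round(3))

# --- protocol rules
print(titrate_fio2(275.0), classify_berlin(275.0).value)
```

prints

```
Raw = 20.3 cmH2O.s/L, G = 392, H = 1963 cmH2O/L
alpha = 0.874, eta = 0.200, residual = 0.0514
          mean  count  volume_ml
region
total    1.739   8744      8.744
well     2.399   4809      4.809
poor     1.200   2186      2.186
non      0.600   1749      1.749
ventral  2.398   4372      4.372
dorsal   1.081   4372      4.372
0.4 mild
```

With 5% proportional measurement noise the fit recovers the programmed
mechanics within ~2%, and the imaging chain returns the programmed
zone uptakes (2.4 / 1.2 / 0.6 SUV) essentially exactly — the whole-lung
mean (1.74) is their voxel-count-weighted average.  A PaO₂/FiO₂ of
275 mmHg maps to the 0.4 FiO₂ tier and grades as mild ARDS.

A full study (four groups at the published sizes, hourly mechanics and
blood gases, one phantom per animal, mixed-model statistics) runs from one
config:

```bash
varivent run-all --config study.yaml      # or: python -m varivent.cli ...
```

with `study.yaml` as produced by `StudyConfig(seed=1).to_yaml("study.yaml")`.
Outputs are tidy CSVs (pattern tables, fitted mechanics and relative-change
trajectories, blood-gas trajectories with titrated FiO₂ and Berlin grades,
regional uptake summaries, ANOVA and post-hoc tables) plus a
`manifest.json` recording the seed, a config hash and output hashes —
identical configs give byte-identical outputs.

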