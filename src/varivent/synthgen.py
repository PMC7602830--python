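"""Synthetic inputs for every stage of the pipeline.

No raw data from the underlying animal study are deposited anywhere, so the
pipeline is exercised end-to-end on synthetic inputs with explicitly
parameterized statistical structure:

* **Breathing references** — surrogates for a whole-body plethysmography
  recording of spontaneously breathing rabbit pups: truncated-Gaussian
  tidal volumes and respiratory rates (bounds 0.5x-1.5x the mean, so no
  non-physical breaths), default VT variability CV 0.15.
* **Impedance spectra** — forward constant-phase model plus independent
  proportional Gaussian perturbations of the real and imaginary parts.
* **Lung phantoms** — co-registered CT/PET/SPECT volumes on an ellipsoidal
  lung mask.  Voxels are assigned to the three aeration zones in
  ventral-to-dorsal order (atelectasis accumulates in the dependent lung)
  with exact zone voxel counts; CT is zone mean + Gaussian jitter clipped to
  the zone's HU bin so segmentation is exact by construction; PET activity
  is built backwards from the target tissue-fraction-normalized uptake, so
  the quantification round-trip recovers the programmed zone means.
* **Longitudinal cohorts** — long-format animal x timepoint x variable
  tables drawn around per-group, per-timepoint effect profiles with a
  Gaussian random intercept per animal (the same structure the mixed model
  fits); positive-skewed variables are drawn moment-matched lognormal.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError
from .imaging import AERATION_BINS, ZONES, VolumeSet, gas_tissue_fraction
from .oscillometry import CPMParameters, ImpedanceSpectrum, cpm_evaluate
from .ventilation import Breath, BreathReference

__all__ = [
    "CohortDesign",
    "synth_breath_reference",
    "synth_impedance",
    "synth_lung_phantom",
    "synth_cohort",
]

#: Inspiratory fraction of the breath cycle used by generated references.
_TI_FRACTION = 1.0 / 3.0


def _truncated_normal(
    rng: np.random.Generator, mean: float, cv: float, n: int, rel_bounds=(0.5, 1.5)
) -> np.ndarray:
    """Draws from N(mean, cv*mean) truncated to rel_bounds * mean."""
    if cv == 0:
        return np.full(n, mean)
    sd = cv * mean
    a = (rel_bounds[0] * mean - mean) / sd
    b = (rel_bounds[1] * mean - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def synth_breath_reference(
    n_breaths: int,
    mean_vt: float = 8.0,
    cv_vt: float = 0.15,
    mean_rr: float = 60.0,
    cv_rr: float = 0.15,
    seed: int = 0,
    rel_bounds: tuple[float, float] = (0.5, 1.5),
) -> BreathReference:
    """Generate a physiological breathing reference.

    Tidal volumes (mL/kg) and respiratory rates (breaths/min) are drawn from
    truncated Gaussians on [rel_bounds[0], rel_bounds[1]] times their mean;
    each breath's cycle time is 60/rr with a fixed 1:2
    inspiratory:expiratory split.
    """
    if n_breaths < 1:
        raise InvalidParameterError("n_breaths must be >= 1")
    if mean_vt <= 0 or mean_rr <= 0:
        raise InvalidParameterError("means must be positive")
    if cv_vt < 0 or cv_rr < 0:
        raise InvalidParameterError("coefficients of variation must be >= 0")
    rng = np.random.default_rng(seed)
    vts = _truncated_normal(rng, mean_vt, cv_vt, n_breaths, rel_bounds)
    rrs = _truncated_normal(rng, mean_rr, cv_rr, n_breaths, rel_bounds)
    cycles = 60.0 / rrs
    breaths = tuple(
        Breath(
            tidal_volume=float(vt),
            inspiratory_time=float(c * _TI_FRACTION),
            expiratory_time=float(c * (1.0 - _TI_FRACTION)),
        )
        for vt, c in zip(vts, cycles)
    )
    return BreathReference(breaths=breaths, source_label=f"synthetic(seed={seed})")


def synth_impedance(
    params: CPMParameters,
    frequencies: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Forward constant-phase spectrum with proportional measurement noise.

    ``noise_sd`` is the relative SD of independent Gaussian perturbations
    applied to the real and imaginary parts; zero returns the exact forward
    model.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    clean = cpm_evaluate(params, frequencies)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    re = clean.z.real * (1.0 + noise_sd * rng.standard_normal(len(clean)))
    im = clean.z.imag * (1.0 + noise_sd * rng.standard_normal(len(clean)))
    return ImpedanceSpectrum(frequencies=clean.frequencies, z=re + 1j * im)


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned ellipsoid filling ~80% of each dimension."""
    grids = np.meshgrid(
        *[np.arange(s) - (s - 1) / 2.0 for s in shape], indexing="ij"
    )
    radii = [0.4 * s for s in shape]
    r2 = sum((g / r) ** 2 for g, r in zip(grids, radii))
    return r2 <= 1.0


def _zone_bin(index: int) -> tuple[float, float]:
    return AERATION_BINS[index], AERATION_BINS[index + 1]


def synth_lung_phantom(
    shape: tuple[int, int, int] = (40, 40, 40),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    zone_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    zone_hu_means: tuple[float, float, float] = (-800.0, -300.0, 0.0),
    zone_uptake_means: tuple[float, float, float] = (2.0, 1.0, 0.5),
    spect_uptake_means: tuple[float, float, float] | None = None,
    dose: float = 37_000.0,
    weight: float = 670.0,
    hu_jitter_sd: float = 30.0,
    uptake_cv: float = 0.05,
    gravity_axis: int = 2,
    seed: int = 0,
) -> VolumeSet:
    """Build a co-registered CT/PET/SPECT lung phantom.

    Mask voxels are assigned to the well/poor/non-aerated zones in
    ventral-to-dorsal order along ``gravity_axis``, with zone voxel counts
    equal to ``zone_fractions`` times the mask size up to rounding (within
    one voxel).  CT voxels get their zone's HU mean plus Gaussian jitter
    (``hu_jitter_sd``) clipped inside the zone's radiodensity bin, so
    aeration segmentation recovers the programmed composition exactly.

    PET activity (kBq/mL) is constructed backwards from the target
    normalized uptake: for a voxel in zone z with tissue fraction f_t,
    activity = uptake_z * (1 + jitter) * f_t * dose / weight, so SUV
    computation followed by tissue-fraction normalization returns the
    programmed ``zone_uptake_means`` (``uptake_cv`` sets mean-preserving
    relative jitter).  SPECT is built the same way from
    ``spect_uptake_means`` (default: a perfusion-like pattern, higher in the
    aerated lung).
    """
    if abs(sum(zone_fractions) - 1.0) > 1e-9:
        raise InvalidParameterError("zone fractions must sum to 1")
    if any(f < 0 for f in zone_fractions):
        raise InvalidParameterError("zone fractions must be >= 0")
    for i, hu in enumerate(zone_hu_means):
        lo, hi = _zone_bin(i)
        inside = lo <= hu < hi or (i == len(ZONES) - 1 and lo <= hu <= hi)
        if zone_fractions[i] > 0 and not inside:
            raise InvalidParameterError(
                f"HU mean {hu} for zone {ZONES[i]!r} outside its bin [{lo}, {hi})"
            )
    if dose <= 0 or weight <= 0:
        raise InvalidParameterError("dose and weight must be positive")
    if uptake_cv < 0 or hu_jitter_sd < 0:
        raise InvalidParameterError("jitter parameters must be >= 0")
    if spect_uptake_means is None:
        spect_uptake_means = (1.3, 0.9, 0.7)

    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape)
    n_mask = int(mask.sum())

    # stable ventral->dorsal ordering of mask voxels
    coords = np.argwhere(mask)
    order = np.argsort(coords[:, gravity_axis], kind="stable")
    sorted_idx = coords[order]

    counts = [int(round(f * n_mask)) for f in zone_fractions]
    counts[-1] = n_mask - sum(counts[:-1])
    if counts[-1] < 0:
        raise InvalidParameterError("zone fractions incompatible with mask size")

    zone_of = np.zeros(n_mask, dtype=int)
    start = 0
    for z, c in enumerate(counts):
        zone_of[start : start + c] = z
        start += c

    ct = np.full(shape, -1000.0)
    pet = np.zeros(shape)
    spect = np.zeros(shape)
    for z in range(len(ZONES)):
        sel = sorted_idx[zone_of == z]
        if sel.size == 0:
            continue
        ix = tuple(sel.T)
        lo, hi = _zone_bin(z)
        hu = zone_hu_means[z] + hu_jitter_sd * rng.standard_normal(len(sel))
        # keep jitter strictly inside the bin so labels stay exact
        hu = np.clip(hu, lo, np.nextafter(hi, lo) if z < len(ZONES) - 1 else hi)
        ct[ix] = hu
        _, f_tissue = gas_tissue_fraction(hu)
        for target, out in ((zone_uptake_means[z], pet), (spect_uptake_means[z], spect)):
            jitter = 1.0 + uptake_cv * rng.standard_normal(len(sel))
            normalized = np.maximum(target * jitter, 0.0)
            out[ix] = normalized * f_tissue * (dose / weight)

    return VolumeSet(
        ct=ct,
        pet=pet,
        spect=spect,
        mask=mask,
        spacing=spacing,
        gravity_axis=gravity_axis,
        dorsal_is_high=True,
    )


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic longitudinal cohort.

    effect_profile maps variable -> group -> timepoint -> (mean, sd), where
    sd is the residual dispersion of single measurements.  intercept_sd is
    the SD of the Gaussian animal-level random intercept (per variable or a
    single value for all).  Variables listed in ``lognormal_variables`` are
    drawn moment-matched lognormal instead of normal.  ``variables``
    optionally declares the permitted outcome names.
    """

    groups: tuple[str, ...]
    n_per_group: int | dict[str, int]
    timepoints: tuple[str, ...]
    effect_profile: dict
    seed: int
    intercept_sd: float | dict[str, float] = 0.0
    lognormal_variables: frozenset = frozenset()
    variables: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(self.groups) < 1 or len(self.timepoints) < 1:
            raise InvalidParameterError("groups and timepoints must be non-empty")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise InvalidParameterError("timepoints must be unique and ordered")
        for g in self.groups:
            if self.group_n(g) < 2:
                raise InvalidParameterError("n_per_group must be >= 2")
        if self.variables is not None:
            unknown = set(self.effect_profile) - set(self.variables)
            if unknown:
                raise InvalidParameterError(
                    f"unknown variable(s) in effect_profile: {sorted(unknown)}"
                )
        for var, per_group in self.effect_profile.items():
            for g in self.groups:
                if g not in per_group:
                    raise InvalidParameterError(f"{var!r}: missing group {g!r}")
                for t in self.timepoints:
                    if t not in per_group[g]:
                        raise InvalidParameterError(
                            f"{var!r}/{g!r}: missing timepoint {t!r}"
                        )
                    mean, sd = per_group[g][t]
                    if not np.isfinite(mean) or not np.isfinite(sd) or sd < 0:
                        raise InvalidParameterError(
                            f"{var!r}/{g!r}/{t!r}: need finite mean and sd >= 0"
                        )

    def group_n(self, group: str) -> int:
        if isinstance(self.n_per_group, dict):
            if group not in self.n_per_group:
                raise InvalidParameterError(f"no sample size for group {group!r}")
            return int(self.n_per_group[group])
        return int(self.n_per_group)

    def var_intercept_sd(self, variable: str) -> float:
        if isinstance(self.intercept_sd, dict):
            return float(self.intercept_sd.get(variable, 0.0))
        return float(self.intercept_sd)


def _split_group(group: str) -> tuple[str, str]:
    """Group label 'PCV-CTRL' -> (mode, condition); tolerant of other labels."""
    if "-" in group:
        mode, condition = group.split("-", 1)
        return mode, condition
    return group, group


def _lognormal_values(
    rng: np.random.Generator,
    mean: float,
    sd_resid: float,
    sd_intercept: float,
    intercept_u: float,
    n: int,
) -> np.ndarray:
    """Lognormal draws moment-matched to (mean, sqrt(sd_resid^2+sd_intercept^2)),
    with the animal effect entering as a shared log-scale component.
    ``intercept_u`` is the animal's standard-normal intercept draw."""
    var_total = sd_resid**2 + sd_intercept**2
    if mean <= 0:
        raise InvalidParameterError("lognormal variables need positive means")
    if var_total == 0:
        return np.full(n, mean)
    s2_total = np.log1p(var_total / mean**2)
    share_int = sd_intercept**2 / var_total
    s_int = np.sqrt(s2_total * share_int)
    s_res = np.sqrt(s2_total * (1.0 - share_int))
    mu = np.log(mean) - s2_total / 2.0
    return np.exp(mu + s_int * intercept_u + s_res * rng.standard_normal(n))


def synth_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw a long-format cohort table from a :class:`CohortDesign`.

    One row per (animal, timepoint, variable) with columns animal_id, group,
    mode, condition, timepoint, variable, value.  Normal variables are
    mean + intercept_i + residual; the intercept is shared by an animal
    across timepoints of the same variable.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for variable in design.effect_profile:
        sd_int = design.var_intercept_sd(variable)
        lognormal = variable in design.lognormal_variables
        for group in design.groups:
            mode, condition = _split_group(group)
            profile = design.effect_profile[variable][group]
            for i in range(design.group_n(group)):
                animal = f"{group}-{i + 1:02d}"
                u = rng.standard_normal()  # animal intercept, standard-normal
                if lognormal:
                    means = np.array([profile[t][0] for t in design.timepoints])
                    sds = np.array([profile[t][1] for t in design.timepoints])
                    values = np.array(
                        [
                            _lognormal_values(rng, m, s, sd_int, u, 1)[0]
                            for m, s in zip(means, sds)
                        ]
                    )
                else:
                    values = np.array(
                        [
                            profile[t][0]
                            + sd_int * u
                            + profile[t][1] * rng.standard_normal()
                            for t in design.timepoints
                        ]
                    )
                for t, v in zip(design.timepoints, values):
                    rows.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "mode": mode,
                            "condition": condition,
                            "timepoint": t,
                            "variable": variable,
                            "value": float(v),
                        }
                    )
    return pd.DataFrame(rows)
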