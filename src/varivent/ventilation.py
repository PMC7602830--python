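"""Ventilation patterns and protocol rules.

Two modes are modelled.  Pressure-controlled ventilation (PCV) delivers
monotonous, identical breaths.  Physiologically variable ventilation (PVV)
replays a pre-recorded natural breathing pattern — here a surrogate for a
whole-body plethysmography recording of spontaneously breathing rabbit pups —
cyclically, with one global tidal-volume rescaling so the pattern mean hits
the protocol target (8 mL/kg by default) while the breath-to-breath relative
variability of the recording is preserved exactly.

The module also implements the bedside rules of the study protocol as pure
functions: the four-tier FiO2 titration on the PaO2/FiO2 ratio, the Berlin
ARDS severity grading, the ARDS-induction stopping rule (halt when PaO2/FiO2
first enters 250-300 mmHg), a proportional respiratory-rate controller
targeting normocapnia (end-tidal CO2 5.5-6%), the driving-pressure identity,
and MAP/HR extraction from recorded pressure and ECG waveforms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidParameterError, UndefinedResultError

__all__ = [
    "Mode",
    "Severity",
    "Breath",
    "BreathReference",
    "BreathingPattern",
    "VentilatorState",
    "BloodGasRecord",
    "generate_pvv_pattern",
    "generate_pcv_pattern",
    "titrate_fio2",
    "classify_berlin",
    "ards_induction_stop",
    "titrate_rr_normocapnia",
    "driving_pressure",
    "hemodynamic_summary",
]

#: FiO2 titration tiers on PaO2/FiO2 (mmHg): half-open bins (lo, hi] with the
#: upper edge belonging to the lower tier; the table is the single source of
#: truth for the rule.
FIO2_TIERS: tuple[tuple[float, float, float], ...] = (
    (250.0, float("inf"), 0.4),
    (200.0, 250.0, 0.6),
    (100.0, 200.0, 0.8),
    (0.0, 100.0, 0.9),
)

#: PaO2/FiO2 window (mmHg, inclusive) at which ARDS induction stops.
ARDS_TARGET_WINDOW: tuple[float, float] = (250.0, 300.0)

#: Normocapnia band for end-tidal CO2 (%).
ETCO2_BAND: tuple[float, float] = (5.5, 6.0)


class Mode(str, enum.Enum):
    PCV = "PCV"
    PVV = "PVV"


class Severity(str, enum.Enum):
    """Berlin ARDS severity grades from the PaO2/FiO2 ratio."""

    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class Breath:
    """One delivered breath: tidal volume (mL/kg) and timing (s)."""

    tidal_volume: float
    inspiratory_time: float
    expiratory_time: float

    def __post_init__(self):
        if self.tidal_volume <= 0:
            raise InvalidParameterError("tidal volume must be positive")
        if self.inspiratory_time <= 0 or self.expiratory_time <= 0:
            raise InvalidParameterError("breath durations must be positive")

    @property
    def duration(self) -> float:
        return self.inspiratory_time + self.expiratory_time


@dataclass(frozen=True)
class BreathReference:
    """Pre-recorded breathing pattern replayed by the PVV mode."""

    breaths: tuple[Breath, ...]
    source_label: str = "synthetic"

    def __post_init__(self):
        if len(self.breaths) < 1:
            raise InvalidParameterError("breath reference must contain >= 1 breath")
        object.__setattr__(self, "breaths", tuple(self.breaths))

    def tidal_volumes(self) -> np.ndarray:
        return np.array([b.tidal_volume for b in self.breaths])

    def durations(self) -> np.ndarray:
        return np.array([b.duration for b in self.breaths])


@dataclass(frozen=True)
class BreathingPattern:
    """Ordered breath sequence driving one ventilation mode."""

    breaths: tuple[Breath, ...]
    mode: Mode
    peep: float
    target_mean_vt: float

    def __post_init__(self):
        if len(self.breaths) < 1:
            raise InvalidParameterError("pattern must contain >= 1 breath")
        if self.peep < 0:
            raise InvalidParameterError("PEEP must be >= 0")
        object.__setattr__(self, "breaths", tuple(self.breaths))

    def tidal_volumes(self) -> np.ndarray:
        return np.array([b.tidal_volume for b in self.breaths])

    def durations(self) -> np.ndarray:
        return np.array([b.duration for b in self.breaths])

    def to_frame(self) -> pd.DataFrame:
        """Serializable table (breath_index, vt_ml_per_kg, ti_s, te_s)."""
        return pd.DataFrame(
            {
                "breath_index": np.arange(len(self.breaths)),
                "vt_ml_per_kg": [b.tidal_volume for b in self.breaths],
                "ti_s": [b.inspiratory_time for b in self.breaths],
                "te_s": [b.expiratory_time for b in self.breaths],
            }
        )


@dataclass(frozen=True)
class VentilatorState:
    """Current ventilator settings."""

    fio2: float
    rr: float
    peep: float
    inspiratory_pressure: float

    def __post_init__(self):
        if not 0.21 <= self.fio2 <= 1.0:
            raise InvalidParameterError("FiO2 must lie in [0.21, 1.0]")
        if self.rr <= 0:
            raise InvalidParameterError("respiratory rate must be positive")
        if self.peep < 0 or self.inspiratory_pressure < self.peep:
            raise InvalidParameterError("need inspiratory_pressure >= peep >= 0")


@dataclass(frozen=True)
class BloodGasRecord:
    """Arterial blood-gas sample; pf_ratio is derived as pao2/fio2."""

    pao2: float
    paco2: float
    ph: float
    lactate: float
    fio2: float
    pf_ratio: float = field(init=False)

    def __post_init__(self):
        if self.pao2 <= 0 or self.paco2 <= 0:
            raise InvalidParameterError("blood-gas pressures must be positive")
        if not 0.21 <= self.fio2 <= 1.0:
            raise InvalidParameterError("FiO2 must lie in [0.21, 1.0]")
        object.__setattr__(self, "pf_ratio", self.pao2 / self.fio2)


def generate_pvv_pattern(
    reference: BreathReference,
    target_mean_vt: float,
    n_breaths: int,
    peep: float,
) -> BreathingPattern:
    """Build a PVV pattern by cyclic replay of the recorded reference.

    All tidal volumes are rescaled by one global factor so the mean VT of the
    emitted pattern equals ``target_mean_vt`` exactly; timing is replayed
    unchanged.  Because the rescaling is a single multiplicative constant, the
    coefficient of variation of VT (and of breath duration) is preserved
    exactly from the reference.
    """
    if target_mean_vt <= 0:
        raise InvalidParameterError("target mean VT must be positive")
    if n_breaths < 1:
        raise InvalidParameterError("n_breaths must be >= 1")
    ref = reference.breaths
    replay = [ref[i % len(ref)] for i in range(n_breaths)]
    vts = np.array([b.tidal_volume for b in replay])
    scale = target_mean_vt / vts.mean()
    breaths = tuple(
        Breath(
            tidal_volume=b.tidal_volume * scale,
            inspiratory_time=b.inspiratory_time,
            expiratory_time=b.expiratory_time,
        )
        for b in replay
    )
    return BreathingPattern(
        breaths=breaths, mode=Mode.PVV, peep=peep, target_mean_vt=target_mean_vt
    )


def generate_pcv_pattern(
    vt: float, rr: float, n_breaths: int, peep: float, ie_ratio: float = 0.5
) -> BreathingPattern:
    """Monotonous PCV pattern: identical breaths, total cycle time 60/rr s.

    ``ie_ratio`` is the inspiratory fraction Ti/(Ti+Te); the default 0.5
    splits the cycle evenly.
    """
    if vt <= 0 or rr <= 0 or n_breaths < 1:
        raise InvalidParameterError("vt, rr and n_breaths must be positive")
    if not 0 < ie_ratio < 1:
        raise InvalidParameterError("ie_ratio must lie in (0, 1)")
    cycle = 60.0 / rr
    breath = Breath(
        tidal_volume=vt,
        inspiratory_time=cycle * ie_ratio,
        expiratory_time=cycle * (1.0 - ie_ratio),
    )
    return BreathingPattern(
        breaths=(breath,) * n_breaths, mode=Mode.PCV, peep=peep, target_mean_vt=vt
    )


def titrate_fio2(pf_ratio: float) -> float:
    """Four-tier FiO2 rule on the PaO2/FiO2 ratio (mmHg).

    (250, inf) -> 0.4; (200, 250] -> 0.6; (100, 200] -> 0.8; (0, 100] -> 0.9.
    Upper edges belong to the lower-FiO2 tier (half-open bins).
    """
    if not np.isfinite(pf_ratio) or pf_ratio <= 0:
        raise InvalidParameterError("PaO2/FiO2 ratio must be positive and finite")
    for lo, hi, fio2 in FIO2_TIERS:
        if lo < pf_ratio <= hi or (hi == float("inf") and pf_ratio > lo):
            return fio2
    raise AssertionError("unreachable: tiers cover (0, inf)")  # pragma: no cover


def classify_berlin(pf_ratio: float) -> Severity:
    """Berlin ARDS severity from PaO2/FiO2 (mmHg): >300 none, (200, 300] mild,
    (100, 200] moderate, (0, 100] severe."""
    if not np.isfinite(pf_ratio) or pf_ratio <= 0:
        raise InvalidParameterError("PaO2/FiO2 ratio must be positive and finite")
    if pf_ratio > 300:
        return Severity.NONE
    if pf_ratio > 200:
        return Severity.MILD
    if pf_ratio > 100:
        return Severity.MODERATE
    return Severity.SEVERE


def ards_induction_stop(pf_trajectory: Sequence[float]) -> int | None:
    """First index at which PaO2/FiO2 lies inside the induction target window
    [250, 300] mmHg (inclusive); ``None`` if the window is never reached."""
    traj = np.asarray(pf_trajectory, dtype=float)
    if traj.size == 0:
        raise InvalidParameterError("empty PaO2/FiO2 trajectory")
    lo, hi = ARDS_TARGET_WINDOW
    hits = np.nonzero((traj >= lo) & (traj <= hi))[0]
    return int(hits[0]) if hits.size else None


def titrate_rr_normocapnia(
    etco2: float,
    rr: float,
    gain: float = 8.0,
    rr_bounds: tuple[float, float] = (10.0, 150.0),
) -> float:
    """Proportional respiratory-rate adjustment toward normocapnia.

    Inside the 5.5-6.0% end-tidal CO2 band the rate is left unchanged;
    outside it, rr' = rr + gain * (etco2 - 5.75), i.e. a proportional step
    toward the band midpoint, clamped to ``rr_bounds``.
    """
    if etco2 <= 0 or rr <= 0:
        raise InvalidParameterError("etco2 and rr must be positive")
    lo, hi = ETCO2_BAND
    if lo <= etco2 <= hi:
        return rr
    setpoint = (lo + hi) / 2.0
    return float(np.clip(rr + gain * (etco2 - setpoint), *rr_bounds))


def driving_pressure(inspiratory_pressure: float, peep: float) -> float:
    """Driving pressure = inspiratory plateau pressure - PEEP (cmH2O)."""
    if inspiratory_pressure < peep:
        raise InvalidParameterError("inspiratory pressure must be >= PEEP")
    return inspiratory_pressure - peep


def hemodynamic_summary(
    arterial_pressure: np.ndarray,
    ecg: np.ndarray,
    sampling_rate: float,
) -> tuple[float, float]:
    """MAP and HR from recorded curves.

    MAP is the time average of the arterial-pressure waveform.  HR is
    60 / median inter-peak interval of R-peaks detected by thresholding the
    ECG at mean + 2*SD with a 200 ms refractory period.
    """
    ap = np.asarray(arterial_pressure, dtype=float)
    ecg = np.asarray(ecg, dtype=float)
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling rate must be positive")
    if ap.size < 2 * sampling_rate or ecg.size < 2 * sampling_rate:
        raise InvalidParameterError("waveforms must be at least 2 s long")
    map_ = float(ap.mean())
    threshold = ecg.mean() + 2.0 * ecg.std()
    refractory = max(int(round(0.2 * sampling_rate)), 1)
    peaks, _ = find_peaks(ecg, height=threshold, distance=refractory)
    if peaks.size < 2:
        raise UndefinedResultError("fewer than 2 R-peaks detected; HR undefined")
    intervals = np.diff(peaks) / sampling_rate
    hr = 60.0 / float(np.median(intervals))
    return map_, hr
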