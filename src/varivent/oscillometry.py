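"""Forced-oscillation respiratory mechanics.

Input impedance of the respiratory system is measured with the wave-tube
variant of the forced oscillation technique: the load impedance at the distal
end of a calibrated tube is inferred from the complex pressure ratio measured
at the two ends, through the transmission-line relation

    Z_load = Z0 * sinh(gamma * L) / (P1/P2 - cosh(gamma * L)).

The measured spectra are then decomposed into airway and tissue compartments
with the constant-phase model

    Zrs(omega) = Raw + i*omega*Iaw + (G - i*H) / omega**alpha,
    alpha = (2/pi) * arctan(H / G),   omega = 2*pi*f,

where Raw is airway (Newtonian) resistance, Iaw airway inertance, G tissue
damping and H tissue elastance; eta = G/H is the tissue hysteresivity.  The
tissue compartment has frequency-independent phase -alpha*pi/2, hence the
model's name.  Parameters describe the total respiratory system (lungs plus
chest wall); no chest-wall partitioning is attempted.

Frequencies are carried in Hz at every interface; the angular conversion
omega = 2*pi*f happens only inside the model.  Getting this wrong silently
rescales G and H, so the convention is pinned down by tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidParameterError, UndefinedResultError

__all__ = [
    "ImpedanceSpectrum",
    "CPMParameters",
    "WaveTubeConfig",
    "DEFAULT_FREQUENCIES_HZ",
    "wavetube_impedance",
    "cpm_evaluate",
    "cpm_fit",
    "relative_change",
]

#: Default analysis band: 16 pseudo-logarithmically spaced points, 0.5-20 Hz.
DEFAULT_FREQUENCIES_HZ: np.ndarray = np.round(
    np.geomspace(0.5, 20.0, 16), 4
)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex respiratory input impedance (cmH2O.s/L) on a frequency grid (Hz)."""

    frequencies: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if f.size == 0:
            raise InvalidParameterError("empty frequency list")
        if f.size != z.size:
            raise InvalidParameterError("frequencies and z must have equal length")
        if np.any(f <= 0):
            raise InvalidParameterError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise InvalidParameterError("frequencies must be strictly increasing")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(z))):
            raise InvalidParameterError("spectrum contains non-finite values")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "z", z)

    def __len__(self):
        return self.frequencies.size


@dataclass(frozen=True)
class CPMParameters:
    """Constant-phase model parameters.

    raw : airway resistance, cmH2O.s/L
    iaw : airway inertance, cmH2O.s^2/L
    g   : tissue damping, cmH2O/L
    h   : tissue elastance, cmH2O/L

    ``alpha`` and ``eta`` are derived, not free:
    alpha = (2/pi)*arctan(h/g) in [0, 1]; eta = g/h (hysteresivity).
    """

    raw: float
    iaw: float
    g: float
    h: float

    def __post_init__(self):
        for name in ("raw", "iaw", "g", "h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")

    @property
    def alpha(self) -> float:
        if self.g == 0 and self.h == 0:
            return 0.0
        return (2.0 / np.pi) * np.arctan2(self.h, self.g)

    @property
    def eta(self) -> float:
        if self.h <= 0:
            return float("nan")
        return self.g / self.h


@dataclass(frozen=True)
class WaveTubeConfig:
    """Calibration of the wave tube: characteristic impedance ``z0`` (cmH2O.s/L),
    complex propagation coefficient ``gamma`` (1/m, per analysis frequency) and
    physical tube ``length`` (m)."""

    z0: np.ndarray
    gamma: np.ndarray
    length: float

    def __post_init__(self):
        if self.length <= 0:
            raise InvalidParameterError("tube length must be positive")
        z0 = np.atleast_1d(np.asarray(self.z0, dtype=complex))
        gamma = np.atleast_1d(np.asarray(self.gamma, dtype=complex))
        if z0.size != gamma.size:
            raise InvalidParameterError("z0 and gamma must align per frequency")
        object.__setattr__(self, "z0", z0)
        object.__setattr__(self, "gamma", gamma)


def wavetube_impedance(
    pressure_ratio: np.ndarray,
    frequencies: np.ndarray,
    config: WaveTubeConfig,
    denominator_tol: float = 1e-12,
) -> ImpedanceSpectrum:
    """Load impedance from the proximal/distal pressure transfer function.

    Frequencies where ``|P1/P2 - cosh(gamma*L)|`` falls below
    ``denominator_tol`` correspond to a (near-)infinite load — e.g. a closed
    distal end — and are excluded with a warning rather than propagated as
    infinities.
    """
    ratio = np.atleast_1d(np.asarray(pressure_ratio, dtype=complex))
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if ratio.size != f.size or ratio.size != config.gamma.size:
        raise InvalidParameterError("pressure_ratio, frequencies and config must align")
    if not np.all(np.isfinite(ratio)):
        raise InvalidParameterError("pressure_ratio contains non-finite values")

    gl = config.gamma * config.length
    denom = ratio - np.cosh(gl)
    keep = np.abs(denom) > denominator_tol
    if not np.all(keep):
        warnings.warn(
            f"excluding {int(np.sum(~keep))} frequency point(s) with near-zero "
            "wave-tube denominator (load ~ infinite)",
            stacklevel=2,
        )
    if not np.any(keep):
        raise InvalidParameterError("all frequencies excluded by denominator tolerance")
    z = config.z0[keep] * np.sinh(gl[keep]) / denom[keep]
    return ImpedanceSpectrum(frequencies=f[keep], z=z)


def wavetube_pressure_ratio(
    z_load: np.ndarray, config: WaveTubeConfig
) -> np.ndarray:
    """Forward transfer function P1/P2 = cosh(gamma*L) + Z0*sinh(gamma*L)/Z_load.

    Inverse of :func:`wavetube_impedance`; used to build synthetic wave-tube
    recordings and as the round-trip oracle in tests.
    """
    z_load = np.atleast_1d(np.asarray(z_load, dtype=complex))
    gl = config.gamma * config.length
    return np.cosh(gl) + config.z0 * np.sinh(gl) / z_load


def cpm_evaluate(params: CPMParameters, frequencies: np.ndarray) -> ImpedanceSpectrum:
    """Exact forward evaluation of the constant-phase model.

    When ``g == h == 0`` the exponent alpha is undefined; the tissue term is
    taken as zero by convention and the spectrum reduces to Raw + i*omega*Iaw.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if f.size == 0:
        raise InvalidParameterError("empty frequency list")
    if np.any(f <= 0):
        raise InvalidParameterError("frequencies must be positive")
    omega = 2.0 * np.pi * f
    z = params.raw + 1j * omega * params.iaw
    if params.g > 0 or params.h > 0:
        alpha = params.alpha
        z = z + (params.g - 1j * params.h) / omega**alpha
    return ImpedanceSpectrum(frequencies=f, z=z)


def _cpm_residuals(theta, omega, z_meas, weights):
    raw, iaw, g, h = theta
    z = raw + 1j * omega * iaw
    if g > 0 or h > 0:
        alpha = (2.0 / np.pi) * np.arctan2(h, g)
        z = z + (g - 1j * h) / omega**alpha
    diff = (z - z_meas) * weights
    return np.concatenate([diff.real, diff.imag])


def _default_initial(spectrum: ImpedanceSpectrum) -> CPMParameters:
    """Heuristic starting point: Raw from the real-part floor, H from the
    low-frequency reactance, G = H/3 (eta ~ 0.33), Iaw from the
    high-frequency reactance slope."""
    omega = 2.0 * np.pi * spectrum.frequencies
    re, im = spectrum.z.real, spectrum.z.imag
    raw0 = max(float(np.min(re)), 1e-6)
    h0 = max(float(omega[0] * abs(np.min(im))), 1e-3)
    g0 = h0 / 3.0
    if len(spectrum) >= 2:
        iaw0 = max(float((im[-1] - im[-2]) / (omega[-1] - omega[-2])), 1e-6)
    else:  # pragma: no cover - guarded by the >=4 frequency precondition
        iaw0 = 1e-6
    return CPMParameters(raw=raw0, iaw=iaw0, g=g0, h=h0)


def cpm_fit(
    spectrum: ImpedanceSpectrum,
    initial: CPMParameters | None = None,
    weighting: str = "relative",
    max_nfev: int = 5000,
) -> tuple[CPMParameters, float]:
    """Estimate (Raw, Iaw, G, H) by bounded complex nonlinear least squares.

    Minimizes sum_f |Z_meas - Z_model|^2 / |Z_meas|^2 (``weighting="relative"``,
    the default, which keeps low- and high-frequency points comparable) or the
    unweighted residual (``weighting="uniform"``).  alpha is tied to (G, H),
    leaving four free parameters, so at least four frequencies are required.
    Non-negativity is enforced through box bounds, so exact zeros are
    representable.  Deterministic given the spectrum and starting point.

    Returns the parameter estimates and the final relative residual
    sqrt(sum w|dZ|^2 / sum w|Z|^2).
    """
    if len(spectrum) < 4:
        raise InvalidParameterError("cpm_fit requires at least 4 frequencies")
    if weighting not in ("relative", "uniform"):
        raise InvalidParameterError(f"unknown weighting {weighting!r}")

    omega = 2.0 * np.pi * spectrum.frequencies
    z_meas = spectrum.z
    if weighting == "relative":
        weights = 1.0 / np.abs(z_meas)
    else:
        weights = np.ones_like(omega)

    p0 = initial if initial is not None else _default_initial(spectrum)
    theta0 = np.array([p0.raw, p0.iaw, p0.g, p0.h], dtype=float)
    theta0 = np.maximum(theta0, 0.0)

    result = least_squares(
        _cpm_residuals,
        theta0,
        args=(omega, z_meas, weights),
        bounds=(np.zeros(4), np.full(4, np.inf)),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_nfev,
    )
    params = CPMParameters(*np.maximum(result.x, 0.0))
    scale = float(np.sum((np.abs(z_meas) * weights) ** 2))
    residual = float(np.sqrt(2.0 * result.cost / scale))
    if not result.success:
        raise FitFailureError(
            f"constant-phase fit did not converge: {result.message}",
            last_iterate=params,
        )
    return params, residual


def relative_change(value_t: float, value_t0: float) -> float:
    """Percent change of an outcome relative to its reference timepoint:
    100 * (value_t - value_t0) / value_t0."""
    if value_t0 == 0:
        raise UndefinedResultError("relative change undefined for zero baseline")
    return 100.0 * (value_t - value_t0) / value_t0
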