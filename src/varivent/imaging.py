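"""Quantitative lung CT / PET / SPECT analysis.

CT radiodensity (Hounsfield units, HU) drives two quantifications:

* **Aeration compartments.**  Lung voxels are binned into well aerated
  [-1000, -500), poorly aerated [-500, -100) and non-aerated [-100, +100] HU
  zones — the standard quantitative-CT aeration thresholds.  Bins are
  left-closed, right-open except the final right edge.  Voxels outside
  [-1000, +100] are clipped to the nearest bound before labelling (cone-beam
  scatter tolerance); the clip count is reported.

* **Tissue fraction.**  Each voxel is decomposed linearly between pure gas
  (-1000 HU) and pure tissue (0 HU): f_gas = clamp(-HU/1000, 0, 1),
  f_tissue = 1 - f_gas.

Nuclear activity (kBq/mL) is expressed as the standardized uptake value
SUV = activity / (injected dose / body weight), with tissue density taken as
1 g/mL, then divided by the voxel tissue fraction ("normalized SUV") so that
uptake differences reflect metabolic activity rather than the amount of
parenchyma per voxel.  Voxels with tissue fraction below a floor (default
0.05) are excluded from normalization to bound the divisor; exclusion counts
are kept so analyses remain auditable.

Regions are the three aeration zones, the ventral/dorsal halves (split by a
plane through the lung-mask centroid perpendicular to the gravity axis), and
the whole lung; per-region means, voxel counts, volumes and mean HU (MPV)
are aggregated into a tidy table.  Inputs are assumed co-registered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedResultError

logger = logging.getLogger(__name__)

__all__ = [
    "AERATION_BINS",
    "ZONES",
    "VolumeSet",
    "AerationMap",
    "segment_aeration",
    "gas_tissue_fraction",
    "compute_suv",
    "normalize_uptake",
    "split_ventral_dorsal",
    "regional_summary",
]

#: HU bin edges for the aeration compartments; strictly increasing.
AERATION_BINS: tuple[float, float, float, float] = (-1000.0, -500.0, -100.0, 100.0)

#: Zone label codes inside the aeration map.
ZONES: tuple[str, str, str] = ("well", "poor", "non")
_ZONE_CODE = {name: i + 1 for i, name in enumerate(ZONES)}  # 0 = outside mask


@dataclass
class VolumeSet:
    """Co-registered CT (HU), PET and SPECT (kBq/mL) fields with a lung mask.

    ``gravity_axis`` is the array axis along which gravity acts;
    ``dorsal_is_high`` says whether increasing index runs ventral -> dorsal.
    """

    ct: np.ndarray
    pet: np.ndarray
    spect: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    gravity_axis: int = 2
    dorsal_is_high: bool = True

    def __post_init__(self):
        shapes = {self.ct.shape, self.pet.shape, self.spect.shape, self.mask.shape}
        if len(shapes) != 1:
            raise InvalidParameterError("all fields must share one grid shape")
        if self.mask.sum() == 0:
            raise InvalidParameterError("lung mask is empty")
        if not np.all(np.isfinite(self.ct)):
            raise InvalidParameterError("CT field contains non-finite values")
        if not 0 <= self.gravity_axis < self.ct.ndim:
            raise InvalidParameterError("gravity_axis out of range")
        self.mask = self.mask.astype(bool)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0  # mm^3 -> mL

    def to_nifti(self, out_dir: str | Path, prefix: str = "volume") -> dict[str, Path]:
        """Write CT/PET/SPECT/mask as NIfTI-1 on an identical grid and affine."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.spacing, 1.0])
        paths = {}
        fields = {
            "ct": self.ct.astype(np.float32),
            "pet": self.pet.astype(np.float32),
            "spect": self.spect.astype(np.float32),
            "mask": self.mask.astype(np.uint8),
        }
        for name, data in fields.items():
            path = out_dir / f"{prefix}_{name}.nii"
            nib.save(nib.Nifti1Image(data, affine), str(path))
            paths[name] = path
        return paths


@dataclass
class AerationMap:
    """Integer label field over the lung mask (1 well, 2 poor, 3 non; 0 outside)
    plus the HU thresholds used and the count of clipped artefact voxels."""

    labels: np.ndarray
    thresholds: tuple[float, ...]
    n_clipped: int = 0

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.labels == _ZONE_CODE[zone]

    def zone_counts(self) -> dict[str, int]:
        return {z: int(np.sum(self.labels == _ZONE_CODE[z])) for z in ZONES}


def segment_aeration(
    ct: np.ndarray,
    mask: np.ndarray,
    bins: tuple[float, float, float, float] = AERATION_BINS,
) -> AerationMap:
    """Label lung voxels as well/poorly/non-aerated by HU bins.

    Mask voxels outside [bins[0], bins[-1]] are clipped to the nearest edge
    before labelling; the number of clipped voxels is counted and logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise InvalidParameterError("lung mask is empty")
    hu = np.asarray(ct, dtype=float)
    if not np.all(np.isfinite(hu[mask])):
        raise InvalidParameterError("CT values must be finite on the mask")
    if len(bins) != 4 or np.any(np.diff(bins) <= 0):
        raise InvalidParameterError("bins must be 4 strictly increasing edges")

    values = hu[mask]
    clipped = (values < bins[0]) | (values > bins[-1])
    n_clipped = int(clipped.sum())
    if n_clipped:
        logger.info("segment_aeration: clipped %d artefact voxel(s)", n_clipped)
    values = np.clip(values, bins[0], bins[-1])

    # left-closed, right-open bins; the top edge folds into the last zone
    codes = np.digitize(values, bins[1:3], right=False) + 1
    labels = np.zeros(hu.shape, dtype=np.int8)
    labels[mask] = codes
    return AerationMap(labels=labels, thresholds=tuple(bins), n_clipped=n_clipped)


def gas_tissue_fraction(hu: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Linear gas/tissue mixture of a CT voxel between -1000 HU (pure gas)
    and 0 HU (pure tissue); fractions are clamped to [0, 1] and sum to 1."""
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise InvalidParameterError("HU values must be finite")
    f_gas = np.clip(-hu / 1000.0, 0.0, 1.0)
    return f_gas, 1.0 - f_gas


def compute_suv(
    activity: np.ndarray, injected_dose: float, body_weight: float
) -> np.ndarray:
    """Standardized uptake value: activity / (dose / weight).

    activity in kBq/mL, dose in kBq, weight in g; tissue density 1 g/mL.
    """
    if injected_dose <= 0 or body_weight <= 0:
        raise InvalidParameterError("injected dose and body weight must be positive")
    return np.asarray(activity, dtype=float) / (injected_dose / body_weight)


def normalize_uptake(
    suv: np.ndarray,
    ct: np.ndarray,
    mask: np.ndarray,
    min_tissue_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide SUV by the voxelwise tissue fraction.

    Returns the normalized field (NaN outside the retained voxels) and the
    excluded-voxel mask: mask voxels whose tissue fraction falls below
    ``min_tissue_fraction`` are dropped rather than divided by a near-zero
    denominator.
    """
    if not 0 < min_tissue_fraction < 1:
        raise InvalidParameterError("min_tissue_fraction must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise InvalidParameterError("lung mask is empty")
    _, f_tissue = gas_tissue_fraction(ct)
    excluded = mask & (f_tissue < min_tissue_fraction)
    included = mask & ~excluded
    if included.sum() == 0:
        raise UndefinedResultError("all mask voxels excluded by the tissue-fraction floor")
    if excluded.sum():
        logger.info("normalize_uptake: excluded %d voxel(s)", int(excluded.sum()))
    out = np.full(np.shape(suv), np.nan, dtype=float)
    out[included] = np.asarray(suv, dtype=float)[included] / f_tissue[included]
    return out, excluded


def split_ventral_dorsal(
    mask: np.ndarray, gravity_axis: int = 2, dorsal_is_high: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the lung mask into ventral and dorsal halves.

    The split plane is perpendicular to the gravity axis and passes through
    the mask centroid, so the halves are balanced to within one slice's mask
    count regardless of where the lung sits in the image.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise InvalidParameterError("lung mask is empty")
    coords = np.nonzero(mask)[gravity_axis]
    if np.unique(coords).size < 2:
        raise InvalidParameterError("mask is degenerate (single slice) along gravity axis")
    centroid = coords.mean()
    index = np.arange(mask.shape[gravity_axis])
    shape = [1] * mask.ndim
    shape[gravity_axis] = -1
    high = index.reshape(shape) > centroid
    dorsal = mask & high if dorsal_is_high else mask & ~high
    ventral = mask & ~dorsal
    return ventral, dorsal


def _region_rows(
    region: str,
    region_mask: np.ndarray,
    fields: dict[str, np.ndarray],
    ct: np.ndarray,
    voxel_volume_ml: float,
) -> list[dict]:
    rows = []
    for modality, data in fields.items():
        valid = region_mask & np.isfinite(data)
        count = int(valid.sum())
        if count == 0:
            logger.warning("regional_summary: region %r empty for %s", region, modality)
            mean = np.nan
            mpv = np.nan
        else:
            mean = float(data[valid].mean())
            mpv = float(ct[valid].mean())
        rows.append(
            {
                "region": region,
                "modality": modality,
                "mean": mean,
                "count": count,
                "volume_ml": count * voxel_volume_ml,
                "mpv": mpv,
            }
        )
    return rows


def regional_summary(
    volumes: VolumeSet,
    aeration: AerationMap,
    normalized_pet: np.ndarray,
    normalized_spect: np.ndarray,
) -> pd.DataFrame:
    """Aggregate normalized uptake over aeration zones, ventral/dorsal halves
    and the whole lung.

    Returns a tidy table (region, modality, mean, count, volume_ml, mpv).
    Counts refer to voxels with a finite normalized value, so the count-
    weighted zone means reconstruct the whole-lung mean exactly; empty
    regions are reported as NaN (undefined), never as zero.
    """
    mask = volumes.mask
    fields = {"pet": np.asarray(normalized_pet), "spect": np.asarray(normalized_spect)}
    for data in fields.values():
        if data.shape != mask.shape:
            raise InvalidParameterError("normalized fields must match the mask grid")
    ventral, dorsal = split_ventral_dorsal(
        mask, volumes.gravity_axis, volumes.dorsal_is_high
    )
    regions: dict[str, np.ndarray] = {
        "total": mask,
        **{z: aeration.zone_mask(z) for z in ZONES},
        "ventral": ventral,
        "dorsal": dorsal,
    }
    rows: list[dict] = []
    for region, region_mask in regions.items():
        rows.extend(
            _region_rows(region, region_mask, fields, volumes.ct, volumes.voxel_volume_ml)
        )
    return pd.DataFrame(rows)
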