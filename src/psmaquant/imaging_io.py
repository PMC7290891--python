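"""Reading, writing and construction of SUV volumes.

A PET scan is represented as a :class:`SUVVolume`: a 3-D array of
standardized uptake values (SUV, dimensionless) together with the voxel
spacing in millimetres.  Volumes are stored and processed in a fixed
``(x, y, z)`` axis order with the spacing carried alongside; world-coordinate
orientation handling is deliberately out of scope — phantoms and analyses are
axis-aligned.

The physical coordinate of the centre of voxel ``(i, j, k)`` is
``((i + 0.5) * dx, (j + 0.5) * dy, (k + 0.5) * dz)`` measured from the volume
corner.  All region-of-interest geometry in this package (reference spheres,
cylinders, phantom lesions) uses the voxel-centre-inside-shape membership
rule against this grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SUVVolume",
    "InjectionMeta",
    "GA68_HALF_LIFE_MIN",
    "read_volume",
    "write_volume",
    "activity_to_suv",
]

#: Physical half-life of gallium-68 in minutes.
GA68_HALF_LIFE_MIN = 67.71


@dataclass
class SUVVolume:
    """A 3-D standardized-uptake-value image with voxel spacing in mm."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    patient_id: str | None = None
    timepoint: str | None = None  # "baseline" | "follow-up"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"SUV volume must be 3-D, got shape {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be 3 positive values, got {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("SUV volume contains negative values")
        if self.timepoint is not None and self.timepoint not in ("baseline", "follow-up"):
            raise ValueError(f"timepoint must be 'baseline' or 'follow-up', got {self.timepoint!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (mm³ / 1000)."""
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (mm) of voxel centres, open-grid."""
        axes = [
            (np.arange(n) + 0.5) * s
            for n, s in zip(self.data.shape, self.voxel_size_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def with_data(self, data: np.ndarray) -> "SUVVolume":
        return replace(self, data=data)


@dataclass(frozen=True)
class InjectionMeta:
    """Injection and acquisition metadata needed to convert activity to SUV.

    Times may be given either as :class:`datetime.datetime` or as minutes
    (any common float offset); only their difference is used.
    """

    injected_dose_MBq: float
    body_weight_kg: float
    injection_time: datetime | float
    acquisition_time: datetime | float
    half_life_min: float = GA68_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_dose_MBq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.elapsed_min < 0:
            raise ValueError("acquisition_time must not precede injection_time")

    @property
    def elapsed_min(self) -> float:
        """Minutes between injection and acquisition start."""
        if isinstance(self.injection_time, datetime) and isinstance(self.acquisition_time, datetime):
            return (self.acquisition_time - self.injection_time).total_seconds() / 60.0
        if isinstance(self.injection_time, datetime) or isinstance(self.acquisition_time, datetime):
            raise TypeError("injection_time and acquisition_time must both be datetimes or both numeric")
        return float(self.acquisition_time) - float(self.injection_time)


def read_volume(
    path: str | Path,
    patient_id: str | None = None,
    timepoint: str | None = None,
) -> SUVVolume:
    """Read a NIfTI SUV volume; voxel spacing is taken from the header zooms.

    Raises ``ValueError`` if the header carries no positive spacing or the
    image violates SUV-volume invariants (negative or non-finite voxels).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing in NIfTI header: {zooms}")
    return SUVVolume(data=data, voxel_size_mm=tuple(float(z) for z in zooms),
                     patient_id=patient_id, timepoint=timepoint)


def write_volume(vol: SUVVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing in the header (affine diagonal)."""
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def activity_to_suv(
    activity_bq_per_ml: np.ndarray,
    meta: InjectionMeta,
    voxel_size_mm: tuple[float, float, float],
    **volume_kwargs,
) -> SUVVolume:
    """Convert an activity-concentration volume (Bq/mL) into body-weight SUV.

    SUVbw = concentration [Bq/mL] × body weight [g] / decay-corrected
    injected dose [Bq], with the dose decay-corrected from injection to
    acquisition start:  dose_acq = dose_inj × 2^(−Δt / T½).
    """
    conc = np.asarray(activity_bq_per_ml, dtype=np.float64)
    dose_bq = meta.injected_dose_MBq * 1e6
    decayed_dose_bq = dose_bq * 2.0 ** (-meta.elapsed_min / meta.half_life_min)
    weight_g = meta.body_weight_kg * 1000.0
    suv = conc * weight_g / decayed_dose_bq
    return SUVVolume(data=suv, voxel_size_mm=voxel_size_mm, **volume_kwargs)
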