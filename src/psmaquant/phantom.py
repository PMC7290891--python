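"""Synthetic SUV phantoms and paired-method measurement sets.

Downstream stages (segmentation, biomarkers, agreement) are validated against
data with known ground truth.  Two generators provide that:

``generate_phantom``
    A 3-D SUV volume holding a homogeneous background, one liver-like sphere
    with its own Gaussian voxel statistics (the reference region used to
    derive segmentation thresholds), and hot lesions of analytic shape
    (sphere, ellipsoid, or an axis-aligned box for exact-volume tests).
    Lesions are painted at their peak SUV before an optional Gaussian
    point-spread blur and additive voxel noise, so the pre-degradation
    ground-truth volume is exact integer arithmetic: number of voxels whose
    centre lies inside the shape × voxel volume.

``generate_paired_measurements``
    Paired "method A / method B" values for n patients whose per-pair
    relative differences — (A − B) / ((A + B)/2) × 100, the convention used
    by the agreement module — follow a stated Gaussian, with an optional
    wider outlier component.  True values are log-normal, matching the
    right-skewed tumour-burden distributions seen clinically.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import SUVVolume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PairedMeasurementSpec",
    "LesionTruth",
    "generate_phantom",
    "generate_paired_measurements",
]


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic lesion: analytic shape, location and peak uptake."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_suv: float
    shape: str = "sphere"  # sphere | ellipsoid | box

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "box"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if len(self.center_mm) != 3 or len(self.radii_mm) != 3:
            raise ValueError("center_mm and radii_mm must have 3 components")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be positive")
        if self.shape == "sphere" and len(set(self.radii_mm)) != 1:
            raise ValueError("sphere lesion requires equal radii; use shape='ellipsoid'")

    @classmethod
    def sphere(cls, center_mm, radius_mm: float, peak_suv: float) -> "LesionSpec":
        return cls(tuple(center_mm), (radius_mm,) * 3, peak_suv, "sphere")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic SUV study volume."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 0.5
    liver_center_mm: tuple[float, float, float] | None = None
    liver_radius_mm: float = 40.0
    liver_mean_suv: float = 5.0
    liver_sd_suv: float = 0.5
    lesions: tuple[LesionSpec, ...] = ()
    psf_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if self.background_suv < 0:
            raise ValueError("background_suv must be non-negative")
        if self.psf_sigma_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma_mm and noise_sd must be non-negative")
        if self.liver_radius_mm <= 0 or self.liver_sd_suv < 0:
            raise ValueError("invalid liver parameters")
        extent = [n * v for n, v in zip(self.grid_shape, self.voxel_size_mm)]
        for les in self.lesions:
            if any(not (0 < c < e) for c, e in zip(les.center_mm, extent)):
                raise ValueError(f"lesion centre {les.center_mm} outside grid extent {extent}")


@dataclass(frozen=True)
class LesionTruth:
    """Analytic ground truth for one phantom lesion (pre blur/noise)."""

    lesion_id: int
    voxel_count: int
    volume_cm3: float
    peak_suv: float
    center_mm: tuple[float, float, float]


def _shape_mask(vol_shape, voxel_size_mm, center_mm, radii_mm, shape: str) -> np.ndarray:
    """Boolean mask of voxels whose centre lies inside the analytic shape."""
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(vol_shape, voxel_size_mm)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    if shape == "box":
        return ((np.abs(xx - cx) <= rx)
                & (np.abs(yy - cy) <= ry)
                & (np.abs(zz - cz) <= rz))
    # sphere is the equal-radii ellipsoid
    return (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[SUVVolume, list[LesionTruth]]:
    """Build the phantom volume and its per-lesion ground truth.

    Regions must not overlap (lesion–lesion or lesion–liver): overlap would
    make the per-lesion ground truth ambiguous, so it raises ``ValueError``.
    Voxel order of operations: paint background, liver (Gaussian voxels,
    clipped at 0), lesions at peak SUV; then Gaussian PSF blur (sigma in mm,
    converted per axis to voxels); then i.i.d. Gaussian noise clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    data = np.full(spec.grid_shape, float(spec.background_suv))
    claimed = np.zeros(spec.grid_shape, dtype=bool)

    if spec.liver_center_mm is not None:
        liver = _shape_mask(spec.grid_shape, spec.voxel_size_mm,
                            spec.liver_center_mm, (spec.liver_radius_mm,) * 3, "sphere")
        liver_vals = rng.normal(spec.liver_mean_suv, spec.liver_sd_suv, int(liver.sum()))
        data[liver] = np.clip(liver_vals, 0.0, None)
        claimed |= liver

    truths: list[LesionTruth] = []
    voxel_cm3 = np.prod(spec.voxel_size_mm) / 1000.0
    for i, les in enumerate(spec.lesions, start=1):
        mask = _shape_mask(spec.grid_shape, spec.voxel_size_mm,
                           les.center_mm, les.radii_mm, les.shape)
        if np.any(mask & claimed):
            raise ValueError(f"lesion {i} overlaps the liver or another lesion")
        data[mask] = les.peak_suv
        claimed |= mask
        n_vox = int(mask.sum())
        truths.append(LesionTruth(i, n_vox, float(n_vox * voxel_cm3), les.peak_suv,
                                  tuple(les.center_mm)))

    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / v for v in spec.voxel_size_mm]
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, data.shape)
    data = np.clip(data, 0.0, None)

    return SUVVolume(data=data, voxel_size_mm=spec.voxel_size_mm), truths


@dataclass(frozen=True)
class PairedMeasurementSpec:
    """Generator settings for paired two-method biomarker measurements.

    ``bias_pct``/``sd_pct`` parameterise the Gaussian of per-pair relative
    differences in percent of the pair mean; a fraction ``outlier_fraction``
    of pairs draws its relative difference from a wider Gaussian with SD
    ``outlier_sd_pct`` instead.
    """

    n_patients: int = 21
    log_mean: float = np.log(40.0)  # true burden ~ log-normal, median 40 cm³
    log_sd: float = 1.2
    bias_pct: float = 0.0
    sd_pct: float = 20.0
    outlier_fraction: float = 0.0
    outlier_sd_pct: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.sd_pct < 0 or self.outlier_sd_pct < 0:
            raise ValueError("relative-difference SDs must be non-negative")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")


def generate_paired_measurements(spec: PairedMeasurementSpec) -> pd.DataFrame:
    """Draw paired (value_A, value_B) measurements per patient.

    ``value_A`` is log-normal; ``value_B`` is derived so that the pair's
    relative difference d = (A − B)/((A + B)/2) × 100 equals the sampled
    Gaussian deviate exactly:  B = A · (200 − d) / (200 + d).

    Returns a DataFrame with columns patient_id, value_A, value_B.
    """
    rng = np.random.default_rng(spec.seed)
    value_a = rng.lognormal(spec.log_mean, spec.log_sd, spec.n_patients)
    is_outlier = rng.random(spec.n_patients) < spec.outlier_fraction
    sd = np.where(is_outlier, spec.outlier_sd_pct, spec.sd_pct)
    d = spec.bias_pct + rng.standard_normal(spec.n_patients) * sd
    value_b = value_a * (200.0 - d) / (200.0 + d)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:03d}" for i in range(spec.n_patients)],
        "value_A": value_a,
        "value_B": value_b,
    })
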