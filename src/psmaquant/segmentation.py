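"""Reference-region thresholds and lesion extraction.

The segmentation threshold is derived from normal-tissue uptake, following
PERCIST-style practice for PSMA PET:

* liver reference — a 3 cm diameter sphere placed in healthy liver;
  threshold = 1.5 × mean + 2 × SD of the voxels inside it;
* aortic blood-pool reference — a cylinder of 1 cm diameter extended over
  2 cm along z in the descending thoracic aorta, used when liver metastases
  make the liver unusable; threshold = 2 × mean + 2 × SD.

Everything at or above the threshold (inclusive comparison, so boundary
voxels count as lesion) and not covered by a physiological-uptake exclusion
mask is grouped into connected components under 26-connectivity; each
component becomes one :class:`Lesion` carrying voxel count, volume (cm³),
SUVmean, SUVmax and centroid.  Lesions are ordered by descending SUVmax with
ties broken by ascending centroid (lexicographic), which makes outputs
deterministic.

Reference-region placement is user-supplied (clinically, ROIs are placed by
an operator); there is no automatic organ detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import SUVVolume

__all__ = [
    "ReferenceStats",
    "Lesion",
    "NoMeasurableLesionError",
    "liver_reference",
    "aorta_reference",
    "segment_lesions",
    "hottest_lesion",
    "LIVER_SPHERE_DIAMETER_MM",
    "AORTA_CYLINDER_DIAMETER_MM",
    "AORTA_CYLINDER_Z_EXTENT_MM",
]

LIVER_SPHERE_DIAMETER_MM = 30.0
AORTA_CYLINDER_DIAMETER_MM = 10.0
AORTA_CYLINDER_Z_EXTENT_MM = 20.0

_MIN_REFERENCE_VOXELS = 10

#: 26-connectivity structuring element for 3-D component labelling.
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class NoMeasurableLesionError(ValueError):
    """Raised when an operation requires at least one segmented lesion.

    Downstream, an empty follow-up segmentation maps to the complete-response
    branch of the classification schemes rather than to a failure.
    """


@dataclass(frozen=True)
class ReferenceStats:
    """Statistics of a reference ROI and the threshold derived from them."""

    region_kind: str           # "liver_sphere" | "aorta_cylinder"
    mean_suv: float
    sd_suv: float
    threshold_suv: float
    center_mm: tuple[float, float, float]
    n_voxels: int


@dataclass(frozen=True)
class Lesion:
    """One connected PSMA-positive lesion."""

    lesion_id: int
    voxel_count: int
    volume_cm3: float
    suv_mean: float
    suv_max: float
    centroid_mm: tuple[float, float, float]


def _reference_stats(vol: SUVVolume, mask: np.ndarray, kind: str,
                     center_mm, coeff_mean: float) -> ReferenceStats:
    n = int(mask.sum())
    if n < _MIN_REFERENCE_VOXELS:
        raise ValueError(
            f"{kind} reference ROI covers only {n} voxels "
            f"(< {_MIN_REFERENCE_VOXELS}); enlarge the volume or move the ROI"
        )
    vals = vol.data[mask]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return ReferenceStats(
        region_kind=kind,
        mean_suv=mean,
        sd_suv=sd,
        threshold_suv=coeff_mean * mean + 2.0 * sd,
        center_mm=tuple(float(c) for c in center_mm),
        n_voxels=n,
    )


def _check_inside(center_mm, half_extent_mm, vol: SUVVolume, what: str) -> None:
    extent = [n * s for n, s in zip(vol.shape, vol.voxel_size_mm)]
    for c, h, e in zip(center_mm, half_extent_mm, extent):
        if c - h < 0 or c + h > e:
            raise ValueError(f"{what} at {tuple(center_mm)} extends outside the volume")


def liver_reference(vol: SUVVolume, center_mm) -> ReferenceStats:
    """Liver threshold from a 3 cm sphere: 1.5 × mean + 2 × SD.

    The sphere must lie fully inside the volume and cover ≥ 10 voxels.
    """
    r = LIVER_SPHERE_DIAMETER_MM / 2.0
    _check_inside(center_mm, (r, r, r), vol, "liver reference sphere")
    xx, yy, zz = vol.voxel_centers_mm()
    cx, cy, cz = center_mm
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= r ** 2
    return _reference_stats(vol, mask, "liver_sphere", center_mm, coeff_mean=1.5)


def aorta_reference(vol: SUVVolume, center_mm) -> ReferenceStats:
    """Aortic blood-pool threshold from a 1 cm × 2 cm(z) cylinder: 2 × mean + 2 × SD."""
    r = AORTA_CYLINDER_DIAMETER_MM / 2.0
    hz = AORTA_CYLINDER_Z_EXTENT_MM / 2.0
    _check_inside(center_mm, (r, r, hz), vol, "aorta reference cylinder")
    xx, yy, zz = vol.voxel_centers_mm()
    cx, cy, cz = center_mm
    mask = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2) & (np.abs(zz - cz) <= hz)
    return _reference_stats(vol, mask, "aorta_cylinder", center_mm, coeff_mean=2.0)


def segment_lesions(
    vol: SUVVolume,
    threshold_suv: float,
    exclude: np.ndarray | None = None,
    min_voxels: int = 1,
) -> list[Lesion]:
    """Extract PSMA-positive lesions as supra-threshold connected components.

    Parameters
    ----------
    vol : SUVVolume
    threshold_suv : float
        Segmentation threshold (must be positive); comparison is ``SUV >=``.
    exclude : ndarray of bool, optional
        Physiological-uptake mask (salivary glands, ganglia, bladder ...);
        voxels marked True never join a lesion.  Must match the volume shape.
    min_voxels : int
        Components smaller than this are dropped (default 1 = keep all).

    Returns the (possibly empty) list of lesions, ordered by descending
    SUVmax, ties by ascending centroid.
    """
    if threshold_suv <= 0:
        raise ValueError("threshold_suv must be positive")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    mask = vol.data >= threshold_suv
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != vol.shape:
            raise ValueError(
                f"exclusion mask shape {exclude.shape} != volume shape {vol.shape}"
            )
        mask &= ~exclude
    labels, n_components = ndimage.label(mask, structure=_CONNECTIVITY_26)
    if n_components == 0:
        return []

    voxel_cm3 = vol.voxel_volume_cm3
    ids = np.arange(1, n_components + 1)
    counts = ndimage.sum_labels(mask, labels, ids).astype(int)
    means = ndimage.mean(vol.data, labels, ids)
    maxima = ndimage.maximum(vol.data, labels, ids)
    centroids = ndimage.center_of_mass(mask, labels, ids)

    lesions = []
    for count, mean, mx, centroid in zip(counts, means, maxima, centroids):
        if count < min_voxels:
            continue
        centroid_mm = tuple(
            (float(c) + 0.5) * s for c, s in zip(centroid, vol.voxel_size_mm)
        )
        lesions.append((float(mx), centroid_mm, int(count), float(mean)))

    lesions.sort(key=lambda t: (-t[0], t[1]))
    return [
        Lesion(
            lesion_id=i,
            voxel_count=count,
            volume_cm3=count * voxel_cm3,
            suv_mean=mean,
            suv_max=mx,
            centroid_mm=centroid_mm,
        )
        for i, (mx, centroid_mm, count, mean) in enumerate(lesions, start=1)
    ]


def hottest_lesion(lesions: list[Lesion]) -> Lesion:
    """The lesion with the highest SUVmax (ties: lowest lesion_id).

    Raises :class:`NoMeasurableLesionError` on an empty list — the caller
    decides whether that means complete response or missing data.
    """
    if not lesions:
        raise NoMeasurableLesionError("no measurable lesion")
    return min(lesions, key=lambda l: (-l.suv_max, l.lesion_id))
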