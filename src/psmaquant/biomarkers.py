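"""Whole-body tumour-burden biomarkers and relative change between scans.

Two aggregate biomarkers summarise all segmented lesions of one study:

* PSMA-TV — PSMA-derived tumour volume, the sum of lesion volumes (cm³);
* TL-PSMA — total lesion PSMA, the sum over lesions of
  volume × SUVmean.  Dimensionally this is cm³ × SUV; since SUV is
  dimensionless it is conventionally reported in cm³.

Treatment-induced change of any biomarker X is expressed as the follow-up
value as a percentage of baseline, ratio = X_follow-up / X_baseline × 100.
The signed percentage change sometimes quoted clinically is ratio − 100.
A ratio is undefined when the baseline is zero or either value is missing;
classification then falls to the not-assessable branch downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .segmentation import Lesion, NoMeasurableLesionError, hottest_lesion

__all__ = ["StudyQuant", "RelativeChange", "aggregate", "relative_change"]


@dataclass(frozen=True)
class StudyQuant:
    """Per-patient, per-timepoint whole-body aggregates."""

    patient_id: str | None
    timepoint: str | None
    n_lesions: int
    psma_tv_cm3: float
    tl_psma: float
    hottest_suv_max: float | None  # None when no lesion is measurable
    psa_ng_ml: float | None = None


def aggregate(
    lesions: Sequence[Lesion],
    patient_id: str | None = None,
    timepoint: str | None = None,
    psa_ng_ml: float | None = None,
) -> StudyQuant:
    """Sum per-lesion volume and uptake into PSMA-TV and TL-PSMA.

    An empty lesion list is a valid study (no measurable disease):
    PSMA-TV = TL-PSMA = 0 and the hottest-lesion SUVmax is undefined.
    """
    psma_tv = math.fsum(l.volume_cm3 for l in lesions)
    tl_psma = math.fsum(l.volume_cm3 * l.suv_mean for l in lesions)
    try:
        hottest = hottest_lesion(list(lesions)).suv_max
    except NoMeasurableLesionError:
        hottest = None
    return StudyQuant(
        patient_id=patient_id,
        timepoint=timepoint,
        n_lesions=len(lesions),
        psma_tv_cm3=psma_tv,
        tl_psma=tl_psma,
        hottest_suv_max=hottest,
        psa_ng_ml=psa_ng_ml,
    )


@dataclass(frozen=True)
class RelativeChange:
    """Follow-up value of a biomarker as a percentage of its baseline."""

    quantity: str
    baseline: float | None
    follow_up: float | None
    ratio_pct: float | None
    defined: bool

    @property
    def signed_delta_pct(self) -> float | None:
        """Signed percentage change, ratio − 100 (e.g. ratio 24% → −76%)."""
        return None if self.ratio_pct is None else self.ratio_pct - 100.0


def relative_change(
    baseline: float | None,
    follow_up: float | None,
    quantity: str = "",
) -> RelativeChange:
    """ratio = follow-up / baseline × 100; undefined for zero/missing baseline.

    Negative inputs are rejected — every supported biomarker (PSA, SUVmax,
    PSMA-TV, TL-PSMA) is non-negative by construction.
    """
    for name, v in (("baseline", baseline), ("follow_up", follow_up)):
        if v is not None and v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if baseline is None or follow_up is None or baseline == 0:
        return RelativeChange(quantity, baseline, follow_up, None, False)
    return RelativeChange(quantity, baseline, follow_up,
                          follow_up / baseline * 100.0, True)
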