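"""End-to-end study orchestration.

``run_study`` composes the package's stages into one deterministic report:
per-patient segmentation at two timepoints → whole-body biomarkers →
response classification under the four schemes → between-method agreement
statistics.  Two entry modes feed the same downstream machinery:

* imaging mode — each patient supplies NIfTI SUV volumes per timepoint (and
  per method, if two segmentation configurations are compared); reference
  ROIs are user-placed; biomarkers come out of the segmentation;
* tabular mode — per-patient biomarker values per timepoint/method are read
  directly from a table, the form in which multi-reader or multi-software
  study data usually circulate.

Both modes produce identical classifications when fed the same numbers.
Partial inputs (missing PSA, missing baseline volumes) propagate as NA for
the affected patient and scheme with a logged warning; the run continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementResult, bland_altman
from .biomarkers import aggregate, relative_change
from .imaging_io import read_volume
from .response import (
    AgreementMatrix,
    Category,
    ResponseAssessment,
    Scheme,
    classify_br,
    classify_percist,
    classify_volume,
    cross_tabulate,
)
from .segmentation import aorta_reference, liver_reference, segment_lesions

logger = logging.getLogger("psmaquant")

__all__ = ["PatientVolumes", "RunConfig", "StudyReport", "run_study",
           "studies_from_volumes", "classify_cohort", "agreement_by_marker"]

TIMEPOINTS = ("baseline", "follow-up")

#: Biomarker columns understood by the tabular pipeline.
MARKERS = ("psma_tv_cm3", "tl_psma", "hottest_suv_max")

_MARKER_SCHEME = {"psma_tv_cm3": Scheme.PSMA_TV, "tl_psma": Scheme.TL_PSMA}


@dataclass(frozen=True)
class PatientVolumes:
    """Imaging-mode input for one patient and one method."""

    patient_id: str
    method: str
    volume_paths: Mapping[str, str | Path]  # timepoint -> NIfTI path
    reference: str = "liver"                # liver | aorta
    reference_center_mm: tuple[float, float, float] | None = None
    exclusion_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.reference not in ("liver", "aorta"):
            raise ValueError("reference must be 'liver' or 'aorta'")
        unknown = set(self.volume_paths) - set(TIMEPOINTS)
        if unknown:
            raise ValueError(f"unknown timepoints {unknown}; expected {TIMEPOINTS}")


@dataclass
class RunConfig:
    """Everything needed to run one study end to end."""

    studies: pd.DataFrame | None = None          # tabular mode
    patients: Sequence[PatientVolumes] = ()      # imaging mode
    clinical: pd.DataFrame | None = None         # patient_id, psa_baseline,
                                                 # psa_followup, psa_negative,
                                                 # new_lesion
    min_voxels: int = 1
    rel_diff_denominator: str = "mean"
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.studies is None and not self.patients:
            raise ValueError("RunConfig needs either a studies table or patient volumes")


@dataclass
class StudyReport:
    """All tables and summaries produced by one run."""

    studies: pd.DataFrame
    responses: pd.DataFrame
    matrices: Mapping[str, AgreementMatrix]          # per method
    agreements: Mapping[tuple[str, str], AgreementResult]  # (marker, timepoint)
    summary: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.studies.to_csv(out / "studies.csv", index=False)
        self.responses.to_csv(out / "response.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        logger.info("report written to %s", out)


def studies_from_volumes(
    patients: Sequence[PatientVolumes],
    min_voxels: int = 1,
) -> pd.DataFrame:
    """Segment every supplied volume and aggregate lesions into biomarkers.

    Returns the tabular-mode studies table: one row per patient × timepoint
    × method with PSMA-TV, TL-PSMA, hottest SUVmax, lesion count and the
    threshold used (logged per scan).
    """
    rows = []
    for p in patients:
        for timepoint, path in p.volume_paths.items():
            vol = read_volume(path, patient_id=p.patient_id, timepoint=timepoint)
            if p.reference_center_mm is None:
                raise ValueError(f"patient {p.patient_id}: reference_center_mm required")
            ref_fn = liver_reference if p.reference == "liver" else aorta_reference
            ref = ref_fn(vol, p.reference_center_mm)
            exclude = None
            if p.exclusion_path is not None:
                exclude = read_volume(p.exclusion_path).data > 0
            lesions = segment_lesions(vol, ref.threshold_suv,
                                      exclude=exclude, min_voxels=min_voxels)
            logger.info(
                "patient %s %s [%s]: reference=%s mean=%.3f sd=%.3f "
                "threshold=%.3f -> %d lesion(s)",
                p.patient_id, timepoint, p.method, ref.region_kind,
                ref.mean_suv, ref.sd_suv, ref.threshold_suv, len(lesions),
            )
            q = aggregate(lesions, patient_id=p.patient_id, timepoint=timepoint)
            rows.append({
                "patient_id": p.patient_id,
                "timepoint": timepoint,
                "method": p.method,
                "n_lesions": q.n_lesions,
                "psma_tv_cm3": q.psma_tv_cm3,
                "tl_psma": q.tl_psma,
                "hottest_suv_max": q.hottest_suv_max,
                "threshold_suv": ref.threshold_suv,
            })
    return pd.DataFrame(rows)


def _get(df: pd.DataFrame, **filters) -> pd.Series | None:
    m = pd.Series(True, index=df.index)
    for k, v in filters.items():
        m &= df[k] == v
    sub = df[m]
    if len(sub) == 0:
        return None
    if len(sub) > 1:
        raise ValueError(f"duplicate study rows for {filters}")
    return sub.iloc[0]


def _opt(row, key):
    if row is None or key not in row:
        return None
    v = row[key]
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def _flag(row, key) -> bool:
    """Boolean clinical flag; absent or NaN reads as False."""
    if row is None or key not in row:
        return False
    v = row[key]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return False
    return bool(v)


def classify_cohort(
    studies: pd.DataFrame,
    clinical: pd.DataFrame | None,
    method: str,
) -> list[ResponseAssessment]:
    """Classify every patient under the four schemes for one method.

    Missing inputs degrade to NA for the affected scheme with a warning
    (mirroring how real cohorts carry PSA-negative or non-evaluable
    patients) rather than aborting the run.
    """
    out: list[ResponseAssessment] = []
    sub = studies[studies["method"] == method]
    clin_idx = (clinical.set_index(clinical["patient_id"].astype(str))
                if clinical is not None else None)

    for pid in sorted(sub["patient_id"].astype(str).unique()):
        base = _get(sub, patient_id=pid, timepoint="baseline")
        fu = _get(sub, patient_id=pid, timepoint="follow-up")
        crow = clin_idx.loc[pid] if clin_idx is not None and pid in clin_idx.index else None

        # biochemical response
        if crow is not None:
            try:
                out.append(classify_br(_opt(crow, "psa_baseline"),
                                       _opt(crow, "psa_followup"),
                                       psa_negative=_flag(crow, "psa_negative"),
                                       patient_id=pid))
            except ValueError as exc:
                logger.warning("patient %s: %s; BR -> NA", pid, exc)
                out.append(ResponseAssessment(pid, Scheme.BR, category=Category.NA))

        # PERCIST on the hottest lesion
        new_lesion = _flag(crow, "new_lesion")
        out.append(classify_percist(_opt(base, "hottest_suv_max"),
                                    _opt(fu, "hottest_suv_max"),
                                    new_lesion=new_lesion, patient_id=pid))

        # volume-derived schemes
        for marker, scheme in _MARKER_SCHEME.items():
            rc = relative_change(_opt(base, marker), _opt(fu, marker), marker)
            out.append(classify_volume(scheme, rc, patient_id=pid))
    return out


def agreement_by_marker(
    studies: pd.DataFrame,
    denominator: str = "mean",
) -> dict[tuple[str, str], AgreementResult]:
    """Bland–Altman agreement between the two methods, per marker × timepoint.

    Requires exactly two methods in the studies table; patients present for
    both methods at a timepoint with positive values enter the comparison.
    """
    methods = sorted(studies["method"].unique())
    if len(methods) != 2:
        raise ValueError(f"agreement needs exactly 2 methods, found {methods}")
    m_a, m_b = methods
    results: dict[tuple[str, str], AgreementResult] = {}
    for marker in ("psma_tv_cm3", "tl_psma"):
        for timepoint in TIMEPOINTS:
            a = studies[(studies["method"] == m_a) & (studies["timepoint"] == timepoint)]
            b = studies[(studies["method"] == m_b) & (studies["timepoint"] == timepoint)]
            merged = a.merge(b, on="patient_id", suffixes=("_a", "_b"))
            merged = merged.dropna(subset=[f"{marker}_a", f"{marker}_b"])
            merged = merged[(merged[f"{marker}_a"] + merged[f"{marker}_b"]) > 0]
            if len(merged) < 2:
                logger.warning("agreement %s/%s: fewer than 2 usable pairs, skipped",
                               marker, timepoint)
                continue
            results[(marker, timepoint)] = bland_altman(
                merged[f"{marker}_a"].to_numpy(),
                merged[f"{marker}_b"].to_numpy(),
                denominator=denominator,
            )
    return results


def run_study(config: RunConfig) -> StudyReport:
    """Run the full pipeline and assemble the study report."""
    if config.studies is not None:
        studies = config.studies.copy()
        if "method" not in studies.columns:
            studies["method"] = "default"
    else:
        studies = studies_from_volumes(config.patients, min_voxels=config.min_voxels)

    methods = sorted(studies["method"].astype(str).unique())
    resp_rows = []
    matrices: dict[str, AgreementMatrix] = {}
    for method in methods:
        assessments = classify_cohort(studies, config.clinical, method)
        matrices[method] = cross_tabulate(assessments)
        for a in assessments:
            resp_rows.append({
                "patient_id": a.patient_id,
                "method": method,
                "scheme": a.scheme.value,
                "category": a.category.value,
                "ratio_pct": a.ratio_pct,
            })
    responses = pd.DataFrame(resp_rows)

    agreements: dict[tuple[str, str], AgreementResult] = {}
    if len(methods) == 2:
        agreements = agreement_by_marker(studies, config.rel_diff_denominator)

    summary = {
        "psmaquant_version": __version__,
        "seed": config.seed,
        "n_patients": int(studies["patient_id"].nunique()),
        "methods": methods,
        "category_counts": {
            method: {s.value: {c.value: n for c, n in counts.items()}
                     for s, counts in m.category_counts.items()}
            for method, m in matrices.items()
        },
        "pairwise_disagreements": {
            method: {f"{a.value}|{b.value}": dict(v)
                     for (a, b), v in m.pairwise.items()}
            for method, m in matrices.items()
        },
        "agreement": {
            f"{marker}@{timepoint}": {
                "n_pairs": r.n_pairs,
                "bias_pct": r.bias_pct,
                "sd_pct": r.sd_pct,
                "loa_low_pct": r.loa_low_pct,
                "loa_high_pct": r.loa_high_pct,
                "rc_pct": r.rc_pct,
                "n_outliers": r.n_outliers,
            }
            for (marker, timepoint), r in agreements.items()
        },
    }

    report = StudyReport(studies=studies, responses=responses,
                         matrices=matrices, agreements=agreements,
                         summary=summary)
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report
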