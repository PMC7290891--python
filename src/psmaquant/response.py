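"""Therapy-response classification and cross-scheme agreement.

Four response schemes are implemented, all driven by the follow-up value of
a marker as a percentage of baseline (ratio = follow-up/baseline × 100):

=========  ==========================  =========  ================  ==========================
scheme     CR                          PR         SD                PD
=========  ==========================  =========  ================  ==========================
BR         PSA undetectable at f/u     PSA ≤ 50%  50% < PSA < 125%  PSA ≥ 125%
PERCIST    no malignant uptake at f/u  SUVmax ≤ 70%  70–130% (open)  SUVmax ≥ 130% or new lesion
PSMA-TV    no measurable PSMA-TV       ≤ 70%      70–130% (open)    ≥ 130%
TL-PSMA    no measurable TL-PSMA       ≤ 70%      70–130% (open)    ≥ 130%
=========  ==========================  =========  ================  ==========================

Boundary semantics are exactly as tabulated: inclusive (≤ / ≥) on the PR and
PD sides, strict inequalities for SD, so every defined ratio maps to exactly
one category.  The ±30% band of the imaging schemes reflects the convention
that only changes beyond roughly a third of the baseline burden are treated
as a response or progression signal; BR uses the established −50% / +25%
PSA cut-points.

Patients whose inputs are undefined get category NA: PSA-negative disease
(serum PSA known not to track tumour burden) for BR, and an undefined ratio
(zero or missing baseline) for the marker schemes.  PERCIST's new-lesion
rule overrides the ratio: any new PSMA-avid lesion means progressive
disease, even when the hottest lesion's uptake fell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .biomarkers import RelativeChange, relative_change

__all__ = [
    "Scheme",
    "Category",
    "ResponseAssessment",
    "AgreementMatrix",
    "classify_br",
    "classify_percist",
    "classify_volume",
    "cross_tabulate",
]


class Scheme(str, Enum):
    BR = "BR"
    PERCIST = "PERCIST"
    PSMA_TV = "PSMA_TV"
    TL_PSMA = "TL_PSMA"


class Category(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NA = "NA"


@dataclass(frozen=True)
class ResponseAssessment:
    """One patient's category under one response scheme."""

    patient_id: str
    scheme: Scheme
    category: Category
    ratio_pct: float | None = None
    new_lesion: bool | None = None   # PERCIST only
    psa_negative: bool | None = None  # BR only


def _band(ratio: float, pr_cut: float, pd_cut: float) -> Category:
    if ratio <= pr_cut:
        return Category.PR
    if ratio >= pd_cut:
        return Category.PD
    return Category.SD


def classify_br(
    psa_baseline: float | None,
    psa_follow_up: float | None,
    psa_negative: bool = False,
    patient_id: str = "",
) -> ResponseAssessment:
    """Biochemical response from serum PSA (cut-points 50% / 125%).

    ``psa_negative`` marks PSA-negative disease — PSA does not reflect
    tumour burden for this patient, so no BR classification is made (NA).
    CR is reserved for PSA falling to undetectable (zero) under therapy.
    A missing PSA value without the flag is an error; a zero baseline makes
    the ratio undefined (NA).
    """
    if psa_negative:
        return ResponseAssessment(patient_id, Scheme.BR, Category.NA,
                                  psa_negative=True)
    if psa_baseline is None or psa_follow_up is None:
        raise ValueError(
            f"patient {patient_id!r}: missing PSA value without psa_negative flag"
        )
    rc = relative_change(psa_baseline, psa_follow_up, "PSA")
    if psa_follow_up == 0 and psa_baseline > 0:
        return ResponseAssessment(patient_id, Scheme.BR, Category.CR,
                                  ratio_pct=rc.ratio_pct, psa_negative=False)
    if not rc.defined:
        return ResponseAssessment(patient_id, Scheme.BR, Category.NA,
                                  psa_negative=False)
    return ResponseAssessment(patient_id, Scheme.BR, _band(rc.ratio_pct, 50.0, 125.0),
                              ratio_pct=rc.ratio_pct, psa_negative=False)


def classify_percist(
    suvmax_baseline: float | None,
    suvmax_follow_up: float | None,
    new_lesion: bool = False,
    patient_id: str = "",
) -> ResponseAssessment:
    """Adapted PERCIST from the hottest lesion's SUVmax (cut-points 70% / 130%).

    The hottest lesion is chosen independently per scan, regardless of the
    number of lesions.  ``None`` for the follow-up value means no malignant
    uptake remained (CR branch); ``None`` at baseline means the ratio cannot
    be formed (NA) — unless a new lesion forces PD either way.
    """
    if new_lesion:
        ratio = None
        if suvmax_baseline and suvmax_follow_up is not None:
            ratio = relative_change(suvmax_baseline, suvmax_follow_up, "SUVmax").ratio_pct
        return ResponseAssessment(patient_id, Scheme.PERCIST, Category.PD,
                                  ratio_pct=ratio, new_lesion=True)
    if suvmax_follow_up is None:
        return ResponseAssessment(patient_id, Scheme.PERCIST, Category.CR,
                                  new_lesion=False)
    if suvmax_baseline is None or suvmax_baseline == 0:
        return ResponseAssessment(patient_id, Scheme.PERCIST, Category.NA,
                                  new_lesion=False)
    rc = relative_change(suvmax_baseline, suvmax_follow_up, "SUVmax")
    return ResponseAssessment(patient_id, Scheme.PERCIST, _band(rc.ratio_pct, 70.0, 130.0),
                              ratio_pct=rc.ratio_pct, new_lesion=False)


def classify_volume(
    scheme: Scheme | str,
    ratio: RelativeChange,
    patient_id: str = "",
) -> ResponseAssessment:
    """ΔPSMA-TV / ΔTL-PSMA response (cut-points 70% / 130%).

    Zero follow-up burden is complete response regardless of whether the
    ratio is defined; otherwise an undefined ratio yields NA.
    """
    scheme = Scheme(scheme)
    if scheme not in (Scheme.PSMA_TV, Scheme.TL_PSMA):
        raise ValueError(f"classify_volume expects a volume scheme, got {scheme}")
    if ratio.follow_up == 0 and ratio.baseline not in (None, 0):
        return ResponseAssessment(patient_id, scheme, Category.CR,
                                  ratio_pct=ratio.ratio_pct)
    if not ratio.defined:
        return ResponseAssessment(patient_id, scheme, Category.NA)
    return ResponseAssessment(patient_id, scheme, _band(ratio.ratio_pct, 70.0, 130.0),
                              ratio_pct=ratio.ratio_pct)


@dataclass(frozen=True)
class AgreementMatrix:
    """Cross-scheme category table with disagreement counts.

    ``category_counts[scheme][category]`` tallies classified patients (NA
    patients are counted under NA, not under a response class).  Pairwise
    counts exclude patients who are NA in either scheme of the pair; a
    disagreement is *relevant* when exactly one scheme of the pair calls
    progressive disease.
    """

    patients: tuple[str, ...]
    table: Mapping[str, Mapping[Scheme, Category]]
    category_counts: Mapping[Scheme, Mapping[Category, int]]
    pairwise: Mapping[tuple[Scheme, Scheme], Mapping[str, int]]

    def disagreements(self, a: Scheme | str, b: Scheme | str) -> int:
        return self.pairwise[(Scheme(a), Scheme(b))]["disagreements"]

    def relevant_disagreements(self, a: Scheme | str, b: Scheme | str) -> int:
        return self.pairwise[(Scheme(a), Scheme(b))]["relevant_disagreements"]


def cross_tabulate(assessments: Iterable[ResponseAssessment]) -> AgreementMatrix:
    """Tabulate per-patient categories across schemes and count disagreements."""
    table: dict[str, dict[Scheme, Category]] = {}
    for a in assessments:
        row = table.setdefault(a.patient_id, {})
        if a.scheme in row:
            raise ValueError(f"duplicate assessment for patient {a.patient_id!r}, "
                             f"scheme {a.scheme.value}")
        row[a.scheme] = a.category
    if not table:
        raise ValueError("no assessments supplied")

    patients = tuple(table)
    schemes = sorted({s for row in table.values() for s in row},
                     key=list(Scheme).index)

    category_counts = {
        s: {c: sum(1 for row in table.values() if row.get(s) == c) for c in Category}
        for s in schemes
    }

    pairwise: dict[tuple[Scheme, Scheme], dict[str, int]] = {}
    for a, b in itertools.permutations(schemes, 2):
        n = dis = rel = 0
        for row in table.values():
            ca, cb = row.get(a), row.get(b)
            if ca in (None, Category.NA) or cb in (None, Category.NA):
                continue
            n += 1
            if ca != cb:
                dis += 1
                if (ca == Category.PD) != (cb == Category.PD):
                    rel += 1
        pairwise[(a, b)] = {
            "n_compared": n,
            "disagreements": dis,
            "relevant_disagreements": rel,
        }

    return AgreementMatrix(
        patients=patients,
        table=table,
        category_counts=category_counts,
        pairwise=pairwise,
    )
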