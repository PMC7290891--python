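"""Example cohort data for worked examples and validation.

A published single-centre cohort of 21 metastatic castration-resistant
prostate-cancer (CRPC) patients imaged with ⁶⁸Ga-PSMA PET/CT before and
after taxane chemotherapy, whose tumour burden was quantified independently
with two software tools ("syngo" — a commercial workstation package — and
"fiji" — an open-source plugin).  The per-patient response categories under
the four schemes, and the raw relative changes for the six patients whose
volume-based and biochemical classifications disagreed in a clinically
relevant way (progressive disease versus non-progression), are small public
tables and are embedded here so the classification and agreement machinery
can be exercised on real clinical classifications without any download.

Blank (missing) entries are real features of the cohort: two patients had
PSA-negative disease (no biochemical classification), and one patient's
baseline volumes could not be computed because of tracer extravasation.
"""

from __future__ import annotations

import pandas as pd

from .biomarkers import relative_change
from .response import (
    Category,
    ResponseAssessment,
    Scheme,
    classify_br,
    classify_volume,
)

__all__ = [
    "crpc_cohort_classifications",
    "crpc_discordant_patients",
    "cohort_assessments",
    "classify_discordant_patients",
]

# patient, PERCIST, BR, ΔPSMA-TV (syngo), ΔTL-PSMA (syngo), ΔPSMA-TV (fiji),
# ΔTL-PSMA (fiji), PD-by-new-lesion flag.  None = not classifiable.
_COHORT = [
    (1,  "SD", "SD", "PR", "PR", "PR", "PR", False),
    (2,  "PD", None, "PD", "PD", "PD", "PD", True),
    (3,  "PR", "PR", "PR", "PR", "PR", "PR", False),
    (4,  "PD", "PD", "PR", "PR", "PR", "PR", True),
    (5,  "PR", "PR", "PR", "PR", "PR", "PR", False),
    (6,  "PD", "PD", "PD", "PD", "PD", "PD", True),
    (7,  "PR", "PR", "PR", "PR", "PR", "PR", False),
    (8,  "PD", "PD", "SD", "SD", "SD", "SD", True),
    (9,  "PD", "SD", "SD", "SD", "SD", "SD", False),
    (10, "PD", "SD", "PD", "PD", "PD", "PD", False),
    (11, "PD", "PD", "PD", "PD", "PD", "PD", False),
    (12, "PD", "PD", "PD", "PD", "PD", "PD", True),
    (13, "PD", "PD", "PD", "PD", "PD", "PD", True),
    (14, "PD", "PD", None, None, None, None, True),
    (15, "PD", "PR", "PD", "PD", "PD", "PD", False),
    (16, "PD", "PR", "PR", "PR", "PR", "PR", True),
    (17, "PD", None, "PR", "PR", "PR", "PR", True),
    (18, "PR", "PD", "SD", "SD", "SD", "SD", False),
    (19, "PD", "PD", "PD", "PD", "PD", "PD", True),
    (20, "PD", "PD", "PD", "PD", "PD", "PD", False),
    (21, "PD", "PD", "SD", "SD", "SD", "SD", True),
]

# The six clinically relevant BR vs ΔPSMA-TV discordances:
# patient, BR, ΔPSMA-TV, signed ΔPSA %, signed ΔPSMA-TV %, overall survival
# (days), died during follow-up.
_DISCORDANT = [
    (4,  "PD", "PR", +238.0, -76.0, 216,  True),
    (8,  "PD", "SD", +786.0, -21.0, 235,  True),
    (10, "SD", "PD", +9.0,   +42.0, 1169, False),
    (15, "PR", "PD", -99.0,  +213.0, 720, False),
    (18, "PD", "SD", +291.0, -14.0, 328,  True),
    (21, "PD", "SD", +66.0,  +26.0, 1556, False),
]


def crpc_cohort_classifications() -> pd.DataFrame:
    """Per-patient response categories of the 21-patient CRPC cohort.

    Columns: patient_id, percist, br, psma_tv_syngo, tl_psma_syngo,
    psma_tv_fiji, tl_psma_fiji, new_lesion.  Category columns hold
    "CR"/"PR"/"SD"/"PD" or ``None`` where no classification was possible.
    """
    return pd.DataFrame(
        _COHORT,
        columns=[
            "patient_id", "percist", "br",
            "psma_tv_syngo", "tl_psma_syngo",
            "psma_tv_fiji", "tl_psma_fiji",
            "new_lesion",
        ],
    )


def crpc_discordant_patients() -> pd.DataFrame:
    """The six patients with a relevant BR vs ΔPSMA-TV disagreement.

    Columns: patient_id, br, psma_tv, delta_psa_pct, delta_psma_tv_pct
    (both signed percentages, ratio − 100), os_days, died.  Overall survival
    is carried as pass-through metadata only.
    """
    return pd.DataFrame(
        _DISCORDANT,
        columns=["patient_id", "br", "psma_tv",
                 "delta_psa_pct", "delta_psma_tv_pct", "os_days", "died"],
    )


def cohort_assessments(
    method: str = "syngo",
    schemes: tuple[Scheme, ...] = (Scheme.PERCIST, Scheme.BR,
                                   Scheme.PSMA_TV, Scheme.TL_PSMA),
) -> list[ResponseAssessment]:
    """The cohort's printed categories as :class:`ResponseAssessment` records.

    ``method`` selects which software's volume categories are used
    ("syngo" or "fiji"); missing entries become NA assessments.
    """
    if method not in ("syngo", "fiji"):
        raise ValueError(f"method must be 'syngo' or 'fiji', got {method!r}")
    col = {
        Scheme.PERCIST: "percist",
        Scheme.BR: "br",
        Scheme.PSMA_TV: f"psma_tv_{method}",
        Scheme.TL_PSMA: f"tl_psma_{method}",
    }
    out = []
    for row in crpc_cohort_classifications().itertuples(index=False):
        for scheme in schemes:
            cat = getattr(row, col[scheme])
            out.append(ResponseAssessment(
                patient_id=f"#{row.patient_id}",
                scheme=scheme,
                category=Category(cat) if cat is not None else Category.NA,
                new_lesion=bool(row.new_lesion) if scheme is Scheme.PERCIST else None,
            ))
    return out


def classify_discordant_patients() -> pd.DataFrame:
    """Re-derive the six discordant patients' categories from their raw changes.

    Applies the BR and ΔPSMA-TV rules to the printed signed percentage
    changes (converted to ratios as ratio = 100 + Δ) and returns both the
    computed and the published categories side by side.
    """
    rows = []
    for row in crpc_discordant_patients().itertuples(index=False):
        psa_ratio = 100.0 + row.delta_psa_pct
        tv_ratio = 100.0 + row.delta_psma_tv_pct
        br = classify_br(100.0, psa_ratio, patient_id=f"#{row.patient_id}")
        tv = classify_volume(
            Scheme.PSMA_TV,
            relative_change(100.0, tv_ratio, "PSMA-TV"),
            patient_id=f"#{row.patient_id}",
        )
        rows.append({
            "patient_id": row.patient_id,
            "br_computed": br.category.value,
            "br_published": row.br,
            "psma_tv_computed": tv.category.value,
            "psma_tv_published": row.psma_tv,
        })
    return pd.DataFrame(rows)
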