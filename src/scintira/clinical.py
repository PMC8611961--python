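"""Clinical disease-activity scoring: active joints, DAS28-ESR, categories.

DAS28-ESR combines the tender joint count (TJC28) and swollen joint count
(SJC28) over a fixed 28-joint set with the erythrocyte sedimentation rate
(ESR, mm/h) and the patient global assessment (GH, 0-100 visual analogue
scale):

    DAS28-ESR = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28)
                + 0.70*ln(ESR) + 0.014*GH

Activity categories: low (<= 3.2), moderate (3.2 < s <= 5.1), high (> 5.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import AnalysisError

#: Standard DAS28-ESR coefficients (tender, swollen, ln ESR, global assessment).
DAS28_COEFFS = {"tjc": 0.56, "sjc": 0.28, "ln_esr": 0.70, "gh": 0.014}

LOW_THRESHOLD = 3.2
HIGH_THRESHOLD = 5.1
ACTIVITY_LEVELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class JointClinicalStatus:
    """Tender / swollen examination flags for one joint (both may be set)."""

    joint_id: str
    tender: bool
    swollen: bool


def is_clinically_active(status: JointClinicalStatus) -> bool:
    """A joint is clinically active if tender and/or swollen."""
    return status.tender or status.swollen


def count_joints(statuses) -> tuple[int, int, int]:
    """Return (tjc28, sjc28, n_active) from exactly 28 joint statuses.

    A joint that is both tender and swollen counts in both TJC and SJC but
    only once in the active count.
    """
    statuses = list(statuses)
    if len(statuses) != 28:
        raise AnalysisError(f"expected exactly 28 joint statuses, got {len(statuses)}")
    tjc = sum(1 for s in statuses if s.tender)
    sjc = sum(1 for s in statuses if s.swollen)
    n_active = sum(1 for s in statuses if is_clinically_active(s))
    return tjc, sjc, n_active


def das28_esr(tjc28: int, sjc28: int, esr: float, gh: float) -> float:
    """Evaluate the DAS28-ESR formula; strictly increasing in each input."""
    if not 0 <= tjc28 <= 28:
        raise AnalysisError(f"tjc28 must be in [0, 28], got {tjc28}")
    if not 0 <= sjc28 <= 28:
        raise AnalysisError(f"sjc28 must be in [0, 28], got {sjc28}")
    if esr < 1:
        raise AnalysisError(f"esr must be >= 1 mm/h, got {esr}")
    if not 0 <= gh <= 100:
        raise AnalysisError(f"global assessment must be in [0, 100], got {gh}")
    c = DAS28_COEFFS
    return (
        c["tjc"] * math.sqrt(tjc28)
        + c["sjc"] * math.sqrt(sjc28)
        + c["ln_esr"] * math.log(esr)
        + c["gh"] * gh
    )


def classify_activity(das28: float) -> str:
    """Map a DAS28-ESR score to low / moderate / high disease activity."""
    if das28 < 0:
        raise AnalysisError(f"DAS28-ESR must be >= 0, got {das28}")
    if das28 <= LOW_THRESHOLD:
        return "low"
    if das28 <= HIGH_THRESHOLD:
        return "moderate"
    return "high"


@dataclass
class PatientClinical:
    """Per-patient clinical summary over the 28 DAS28 joints."""

    patient_id: str
    statuses: list[JointClinicalStatus]
    esr: float
    global_assessment: float
    das28_esr: float = field(init=False)
    activity: str = field(init=False)

    def __post_init__(self):
        tjc, sjc, _ = count_joints(self.statuses)
        self.tjc28 = tjc
        self.sjc28 = sjc
        self.das28_esr = das28_esr(tjc, sjc, self.esr, self.global_assessment)
        self.activity = classify_activity(self.das28_esr)


def clinical_table(patients: list[PatientClinical]) -> pd.DataFrame:
    """Per-patient clinical summary as a DataFrame."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "tjc28": [p.tjc28 for p in patients],
            "sjc28": [p.sjc28 for p in patients],
            "esr": [p.esr for p in patients],
            "global_assessment": [p.global_assessment for p in patients],
            "das28_esr": [p.das28_esr for p in patients],
            "activity": [p.activity for p in patients],
        }
    )


def status_table(patients: list[PatientClinical]) -> pd.DataFrame:
    """Per-joint tender/swollen flag table (one row per patient-joint)."""
    rows = []
    for p in patients:
        for s in p.statuses:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "joint_id": s.joint_id,
                    "tender": s.tender,
                    "swollen": s.swollen,
                }
            )
    return pd.DataFrame(rows)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
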