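"""Worker-level raw measurements.

A :class:`WorkerRecord` holds one worker's routine health-examination and
functional-test results in conventional clinical units. Any measurement may
be missing (``None``); downstream coding and fitting define explicit
missing-data behaviour rather than silently treating absence as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Continuous measurement fields, in canonical column order.
CONTINUOUS_FIELDS: tuple[str, ...] = (
    "age",
    "bmi",
    "waist",
    "sbp",
    "dbp",
    "resting_hr",
    "fasting_glucose",
    "hba1c",
    "total_chol",
    "ldl",
    "hdl",
    "triglycerides",
    "ast",
    "alt",
    "ggtp",
    "hemoglobin",
    "pta_0_5_4k",
    "fev1_fvc",
    "fev1_pred",
    "vo2max",
    "pack_years",
    "alcohol_per_week",
)

#: Binary fields (medication use, ECG finding), canonical order.
BINARY_FIELDS: tuple[str, ...] = (
    "on_antihypertensive",
    "on_antidiabetic",
    "on_lipid_lowering",
    "ecg_abnormal",
)


@dataclass
class WorkerRecord:
    """One worker's raw examination data.

    Units: age years; bmi kg/m²; waist cm; sbp/dbp mmHg; resting_hr
    beats/min; fasting_glucose, total_chol, ldl, hdl, triglycerides mg/dL;
    hba1c %; ast/alt/ggtp IU/L; hemoglobin g/dL; pta_0_5_4k dB (pure-tone
    average over 0.5–4 kHz); fev1_fvc % (0–100 scale, not a 0–1 ratio);
    fev1_pred % of predicted; vo2max mL/kg/min; pack_years packs/day·years;
    alcohol_per_week drinking occasions per week.
    """

    id: str
    sex: Optional[str] = None
    age: Optional[float] = None
    bmi: Optional[float] = None
    waist: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    resting_hr: Optional[float] = None
    fasting_glucose: Optional[float] = None
    hba1c: Optional[float] = None
    total_chol: Optional[float] = None
    ldl: Optional[float] = None
    hdl: Optional[float] = None
    triglycerides: Optional[float] = None
    ast: Optional[float] = None
    alt: Optional[float] = None
    ggtp: Optional[float] = None
    hemoglobin: Optional[float] = None
    pta_0_5_4k: Optional[float] = None
    fev1_fvc: Optional[float] = None
    fev1_pred: Optional[float] = None
    vo2max: Optional[float] = None
    pack_years: Optional[float] = None
    alcohol_per_week: Optional[float] = None
    on_antihypertensive: Optional[bool] = None
    on_antidiabetic: Optional[bool] = None
    on_lipid_lowering: Optional[bool] = None
    ecg_abnormal: Optional[bool] = None

    def get(self, name: str):
        return getattr(self, name)


ALL_FIELDS: tuple[str, ...] = tuple(f.name for f in fields(WorkerRecord))
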