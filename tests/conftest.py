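import numpy as np
import pytest

from cssi import CohortParams, WorkerRecord, generate_cohort, load_cutoffs

#: All-normal measurement set: every cutoff rule is comfortably not fired.
HEALTHY = dict(
    age=40.0, bmi=22.0, waist=80.0, sbp=115.0, dbp=75.0, resting_hr=65.0,
    fasting_glucose=90.0, hba1c=5.4, total_chol=180.0, ldl=100.0, hdl=55.0,
    triglycerides=100.0, ast=20.0, alt=20.0, ggtp=20.0, hemoglobin=15.0,
    pta_0_5_4k=10.0, fev1_fvc=85.0, fev1_pred=95.0, vo2max=45.0,
    pack_years=0.0, alcohol_per_week=0.0, on_antihypertensive=False,
    on_antidiabetic=False, on_lipid_lowering=False, ecg_abnormal=False,
)


def make_record(worker_id: str = "w0", sex: str = "male", **overrides
                ) -> WorkerRecord:
    """A healthy worker record with selected fields overridden."""
    kw = dict(HEALTHY)
    if sex == "female":
        kw["hemoglobin"] = 13.5
    kw.update(overrides)
    return WorkerRecord(id=worker_id, sex=sex, **kw)


@pytest.fixture(scope="session")
def cutoffs():
    return load_cutoffs()


@pytest.fixture(scope="session")
def cohort_600():
    """A mid-size synthetic cohort with enough unsuitable workers to fit."""
    return generate_cohort(CohortParams(), 600, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240615)
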