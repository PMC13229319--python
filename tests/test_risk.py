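"""Risk-factor coding: boundary semantics, tiers, categories, missing data."""

import numpy as np
import pytest

from cssi import (
    FACTOR_TIERS,
    FACTORS,
    CodingError,
    ConfigurationError,
    FitnessCategory,
    Vo2maxReference,
    assign_category,
    code_risk_factors,
    vo2max_is_low,
)
from cssi.risk import Vo2maxBand

from .conftest import make_record


@pytest.mark.parametrize(
    "sex, overrides, factor, expected",
    [
        # obesity: BMI >= 25 OR waist >= 90 (m) / >= 85 (f)
        ("male", {"bmi": 25.0, "waist": 80.0}, "obesity", 1),
        ("male", {"bmi": 24.9, "waist": 89.9}, "obesity", 0),
        ("male", {"bmi": 20.0, "waist": 90.0}, "obesity", 1),
        ("female", {"bmi": 20.0, "waist": 85.0}, "obesity", 1),
        ("female", {"bmi": 20.0, "waist": 89.0, "hemoglobin": 13.0}, "obesity", 1),
        # hypertension: SBP >= 140 OR DBP >= 90 OR medication
        ("male", {"sbp": 140.0}, "hypertension", 1),
        ("male", {"dbp": 90.0}, "hypertension", 1),
        ("male", {"sbp": 139.9, "dbp": 89.9}, "hypertension", 0),
        ("male", {"on_antihypertensive": True}, "hypertension", 1),
        # diabetes: glucose >= 126 OR HbA1c >= 6.5 OR medication
        ("male", {"fasting_glucose": 126.0}, "diabetes", 1),
        ("male", {"hba1c": 6.5}, "diabetes", 1),
        ("male", {"hba1c": 6.4, "fasting_glucose": 125.9}, "diabetes", 0),
        ("male", {"on_antidiabetic": True}, "diabetes", 1),
        # dyslipidemia: LDL >= 160 OR HDL < 40 OR TC >= 240 OR medication
        ("male", {"ldl": 160.0}, "dyslipidemia", 1),
        ("male", {"hdl": 40.0}, "dyslipidemia", 0),
        ("male", {"hdl": 39.9}, "dyslipidemia", 1),
        ("male", {"total_chol": 240.0}, "dyslipidemia", 1),
        ("male", {"on_lipid_lowering": True}, "dyslipidemia", 1),
        # liver enzymes: strictly greater than
        ("male", {"ast": 40.0}, "elevated_liver_enzymes", 0),
        ("male", {"ast": 40.1}, "elevated_liver_enzymes", 1),
        ("male", {"alt": 41.0}, "elevated_liver_enzymes", 1),
        ("male", {"ggtp": 50.0}, "elevated_liver_enzymes", 0),
        ("male", {"ggtp": 50.1}, "elevated_liver_enzymes", 1),
        # resting HR: normal band is [50, 100] inclusive
        ("male", {"resting_hr": 50.0}, "abnormal_resting_hr", 0),
        ("male", {"resting_hr": 100.0}, "abnormal_resting_hr", 0),
        ("male", {"resting_hr": 49.9}, "abnormal_resting_hr", 1),
        ("male", {"resting_hr": 100.1}, "abnormal_resting_hr", 1),
        # anemia: Hb < 13 (m) / < 12 (f), strict
        ("male", {"hemoglobin": 12.5}, "anemia", 1),
        ("female", {"hemoglobin": 12.5}, "anemia", 0),
        ("female", {"hemoglobin": 11.9}, "anemia", 1),
        ("male", {"hemoglobin": 13.0}, "anemia", 0),
        # hearing: PTA > 25 dB, strict
        ("male", {"pta_0_5_4k": 25.0}, "hearing_loss", 0),
        ("male", {"pta_0_5_4k": 25.1}, "hearing_loss", 1),
        # pulmonary: FEV1/FVC < 70% OR FEV1 < 80% predicted, strict
        ("male", {"fev1_fvc": 70.0}, "abnormal_pulmonary", 0),
        ("male", {"fev1_fvc": 69.9}, "abnormal_pulmonary", 1),
        ("male", {"fev1_pred": 80.0}, "abnormal_pulmonary", 0),
        ("male", {"fev1_pred": 79.9}, "abnormal_pulmonary", 1),
        # ECG is a plain flag
        ("male", {"ecg_abnormal": True}, "abnormal_ecg", 1),
        # lifestyle: >= cutoffs
        ("male", {"pack_years": 20.0}, "significant_smoking", 1),
        ("male", {"pack_years": 19.9}, "significant_smoking", 0),
        ("male", {"alcohol_per_week": 2.0}, "habitual_alcohol", 1),
        ("male", {"alcohol_per_week": 1.9}, "habitual_alcohol", 0),
    ],
)
def test_cutoff_boundaries(cutoffs, sex, overrides, factor, expected):
    profile = code_risk_factors(make_record(sex=sex, **overrides), cutoffs)
    assert profile.flags[factor] == expected


def test_healthy_worker_has_no_flags(cutoffs):
    profile = code_risk_factors(make_record(), cutoffs)
    assert all(v == 0 for v in profile.flags.values())
    assert profile.total == 0
    assert profile.category is FitnessCategory.SUITABLE


def test_tier_partition_is_7_4_2():
    sizes = {t: sum(1 for v in FACTOR_TIERS.values() if v == t)
             for t in (1, 2, 3)}
    assert sizes == {1: 7, 2: 4, 3: 2}
    assert len(FACTORS) == 13


def test_tier_sums_add_to_total(cutoffs):
    rec = make_record(bmi=30.0, sbp=150.0, vo2max=10.0, pack_years=30.0)
    p = code_risk_factors(rec, cutoffs)
    assert p.tier1_sum == 2 and p.tier2_sum == 1 and p.tier3_sum == 1
    assert p.total == p.tier1_sum + p.tier2_sum + p.tier3_sum == 4
    assert p.category is FitnessCategory.CAUTION


@pytest.mark.parametrize("total, expected", [
    (0, "suitable"), (1, "suitable"), (2, "suitable"), (3, "suitable"),
    (4, "caution"), (5, "caution"),
    (6, "unsuitable"), (7, "unsuitable"), (8, "unsuitable"),
    (9, "unsuitable"), (10, "unsuitable"), (11, "unsuitable"),
    (12, "unsuitable"), (13, "unsuitable"),
])
def test_category_rule_exhaustive(total, expected):
    assert assign_category(total).value == expected


def test_category_rejects_negative_total():
    with pytest.raises(ValueError):
        assign_category(-1)


class TestVo2max:
    def test_exactly_at_bound_is_normal(self, cutoffs):
        ref = cutoffs.vo2max_reference
        bound = ref.lower_bound("male", 40.0)
        assert vo2max_is_low(bound, "male", 40.0, ref) == 0
        assert vo2max_is_low(bound - 1e-9, "male", 40.0, ref) == 1

    def test_zero_vo2max_is_low(self, cutoffs):
        assert vo2max_is_low(0.0, "female", 30.0,
                             cutoffs.vo2max_reference) == 1

    def test_missing_vo2max_returns_missing(self, cutoffs):
        assert vo2max_is_low(None, "male", 40.0,
                             cutoffs.vo2max_reference) is None

    def test_sweep_against_enumerated_toy_reference(self):
        ref = Vo2maxReference(bands={
            "male": [Vo2maxBand(18, 40, 35.0), Vo2maxBand(40, 120, 30.0)],
            "female": [Vo2maxBand(18, 40, 28.0), Vo2maxBand(40, 120, 24.0)],
        })
        # hand-enumerated truth over the band structure
        for sex, age, bound in [("male", 25, 35.0), ("male", 39.9, 35.0),
                                ("male", 40, 30.0), ("male", 80, 30.0),
                                ("female", 18, 28.0), ("female", 55, 24.0)]:
            for v in np.arange(10.0, 50.0, 2.5):
                assert vo2max_is_low(v, sex, age, ref) == int(v < bound)

    def test_band_gap_is_rejected(self):
        with pytest.raises(ConfigurationError, match="gap"):
            Vo2maxReference(bands={
                "male": [Vo2maxBand(18, 40, 35.0), Vo2maxBand(45, 120, 30.0)],
                "female": [Vo2maxBand(18, 120, 28.0)],
            })

    def test_age_outside_coverage_names_the_gap(self, cutoffs):
        with pytest.raises(ConfigurationError, match="coverage"):
            code_risk_factors(make_record(age=150.0), cutoffs)


class TestMissingData:
    def test_all_constituents_missing_marks_flag_missing(self, cutoffs):
        rec = make_record(ldl=None, hdl=None, total_chol=None,
                          on_lipid_lowering=None)
        p = code_risk_factors(rec, cutoffs)
        assert p.flags["dyslipidemia"] is None
        assert p.total == 0  # missing counts as 0 in the sums

    def test_partial_constituents_still_code(self, cutoffs):
        rec = make_record(ldl=None, total_chol=None, hdl=35.0,
                          on_lipid_lowering=None)
        p = code_risk_factors(rec, cutoffs)
        assert p.flags["dyslipidemia"] == 1

    def test_medication_false_with_missing_measurements_codes_zero(self,
                                                                   cutoffs):
        rec = make_record(sbp=None, dbp=None, on_antihypertensive=False)
        p = code_risk_factors(rec, cutoffs)
        assert p.flags["hypertension"] == 0


def test_unknown_sex_raises(cutoffs):
    rec = make_record()
    rec.sex = "other"
    with pytest.raises(CodingError, match="sex"):
        code_risk_factors(rec, cutoffs)


def test_ratio_scale_fev1_fvc_rejected(cutoffs):
    with pytest.raises(CodingError, match="percent"):
        code_risk_factors(make_record(fev1_fvc=0.84), cutoffs)


# --- independent brute-force oracle -------------------------------------

def _oracle_flags(r):
    """Plain re-statement of the cutoff rules, independent of the package."""
    male = r.sex == "male"
    return {
        "obesity": r.bmi >= 25 or r.waist >= (90 if male else 85),
        "hypertension": r.sbp >= 140 or r.dbp >= 90 or r.on_antihypertensive,
        "diabetes": (r.fasting_glucose >= 126 or r.hba1c >= 6.5
                     or r.on_antidiabetic),
        "dyslipidemia": (r.ldl >= 160 or r.hdl < 40 or r.total_chol >= 240
                         or r.on_lipid_lowering),
        "elevated_liver_enzymes": r.ast > 40 or r.alt > 40 or r.ggtp > 50,
        "abnormal_resting_hr": r.resting_hr < 50 or r.resting_hr > 100,
        "anemia": r.hemoglobin < (13 if male else 12),
        "hearing_loss": r.pta_0_5_4k > 25,
        "abnormal_pulmonary": r.fev1_fvc < 70 or r.fev1_pred < 80,
        "abnormal_ecg": bool(r.ecg_abnormal),
        "significant_smoking": r.pack_years >= 20,
        "habitual_alcohol": r.alcohol_per_week >= 2,
    }


def test_coding_matches_brute_force_oracle_on_random_records(cutoffs, rng):
    for i in range(1000):
        sex = "male" if rng.random() < 0.5 else "female"
        rec = make_record(
            worker_id=f"r{i}", sex=sex,
            age=float(rng.uniform(18, 65)),
            bmi=float(rng.uniform(17, 35)),
            waist=float(rng.uniform(60, 110)),
            sbp=float(rng.uniform(90, 180)),
            dbp=float(rng.uniform(55, 110)),
            resting_hr=float(rng.uniform(40, 120)),
            fasting_glucose=float(rng.uniform(70, 200)),
            hba1c=float(rng.uniform(4.5, 9.0)),
            total_chol=float(rng.uniform(120, 300)),
            ldl=float(rng.uniform(50, 220)),
            hdl=float(rng.uniform(25, 90)),
            ast=float(rng.uniform(10, 90)),
            alt=float(rng.uniform(10, 90)),
            ggtp=float(rng.uniform(5, 120)),
            hemoglobin=float(rng.uniform(9, 18)),
            pta_0_5_4k=float(rng.uniform(0, 60)),
            fev1_fvc=float(rng.uniform(50, 95)),
            fev1_pred=float(rng.uniform(50, 120)),
            vo2max=float(rng.uniform(15, 55)),
            pack_years=float(rng.uniform(0, 40)),
            alcohol_per_week=float(rng.uniform(0, 7)),
            on_antihypertensive=bool(rng.random() < 0.2),
            on_antidiabetic=bool(rng.random() < 0.2),
            on_lipid_lowering=bool(rng.random() < 0.2),
            ecg_abnormal=bool(rng.random() < 0.2),
        )
        got = code_risk_factors(rec, cutoffs)
        expected = _oracle_flags(rec)
        for f, want in expected.items():
            assert got.flags[f] == int(want), (f, rec)
        bound = cutoffs.vo2max_reference.lower_bound(rec.sex, rec.age)
        assert got.flags["low_fitness"] == int(rec.vo2max < bound)


# --- monotonicity property ----------------------------------------------

_WORSE = {
    "bmi": 45.0, "waist": 130.0, "sbp": 200.0, "dbp": 130.0,
    "resting_hr": 140.0, "fasting_glucose": 300.0, "hba1c": 12.0,
    "total_chol": 350.0, "ldl": 250.0, "hdl": 10.0, "ast": 200.0,
    "alt": 200.0, "ggtp": 300.0, "hemoglobin": 6.0, "pta_0_5_4k": 80.0,
    "fev1_fvc": 40.0, "fev1_pred": 40.0, "vo2max": 5.0, "pack_years": 60.0,
    "alcohol_per_week": 7.0,
}


def test_worsening_one_measurement_never_lowers_risk(cutoffs, rng):
    """Pushing any single measurement toward its risk direction never
    decreases a flag, the total, or the category severity."""
    for i in range(200):
        sex = "male" if rng.random() < 0.5 else "female"
        base = make_record(
            worker_id=f"m{i}", sex=sex,
            bmi=float(rng.uniform(18, 32)), sbp=float(rng.uniform(100, 160)),
            hdl=float(rng.uniform(30, 80)), ast=float(rng.uniform(10, 60)),
            vo2max=float(rng.uniform(20, 50)),
            pack_years=float(rng.uniform(0, 30)),
        )
        before = code_risk_factors(base, cutoffs)
        field = list(_WORSE)[int(rng.integers(len(_WORSE)))]
        worse = make_record(**{**{k: getattr(base, k) for k in _WORSE},
                               "worker_id": base.id, "sex": sex,
                               field: _WORSE[field]})
        after = code_risk_factors(worse, cutoffs)
        for f in FACTORS:
            assert (after.flags[f] or 0) >= (before.flags[f] or 0)
        assert after.total >= before.total
        assert after.category.severity >= before.category.severity


def test_cutoffs_load_from_yaml_override(tmp_path):
    from cssi import load_cutoffs

    text = (
        "obesity: {bmi_ge: 30.0, waist_ge_male: 102.0, waist_ge_female: 88.0}\n"
        "hypertension: {sbp_ge: 130.0, dbp_ge: 80.0}\n"
        "diabetes: {glucose_ge: 126.0, hba1c_ge: 6.5}\n"
        "dyslipidemia: {ldl_ge: 160.0, hdl_lt: 40.0, total_chol_ge: 240.0}\n"
        "elevated_liver_enzymes: {ast_gt: 40.0, alt_gt: 40.0, ggtp_gt: 50.0}\n"
        "abnormal_resting_hr: {hr_lt: 50.0, hr_gt: 100.0}\n"
        "anemia: {hb_lt_male: 13.0, hb_lt_female: 12.0}\n"
        "hearing_loss: {pta_gt: 25.0}\n"
        "abnormal_pulmonary: {fev1_fvc_lt: 70.0, fev1_pred_lt: 80.0}\n"
        "significant_smoking: {pack_years_ge: 20.0}\n"
        "habitual_alcohol: {times_per_week_ge: 2.0}\n"
    )
    path = tmp_path / "cutoffs.yaml"
    path.write_text(text)
    cfg = load_cutoffs(path)
    p = code_risk_factors(make_record(bmi=26.0, sbp=132.0), cfg)
    assert p.flags["obesity"] == 0      # US-style override: BMI >= 30
    assert p.flags["hypertension"] == 1  # stricter override: SBP >= 130
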