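"""Tiered dichotomous risk-factor coding and the rule-based fitness category.

Thirteen risk factors are coded 0/1 from a worker's raw measurements using
fixed clinical cutoffs. They are organised in three tiers:

* Tier 1 — anthropometric and metabolic (obesity, hypertension, diabetes,
  dyslipidemia, elevated liver enzymes, abnormal resting heart rate, anemia);
* Tier 2 — functional and physiological (hearing loss, abnormal pulmonary
  function, abnormal ECG, low cardiorespiratory fitness);
* Tier 3 — lifestyle (significant smoking history, habitual alcohol use).

Each factor is a disjunction of elementary threshold conditions (e.g.
hypertension fires on SBP ≥ 140 mmHg OR DBP ≥ 90 mmHg OR antihypertensive
medication). Boundary operators are taken literally from the cutoff table:
``≥`` cutoffs fire at the threshold, ``>``/``<`` cutoffs are strict.

Missing data: a disjunction is evaluated over the constituents that are
present; it is 1 as soon as any present constituent fires, 0 if at least one
constituent is present and none fires, and *missing* only when every
constituent is absent. Missing flags count as 0 in tier sums (a warning is
logged), which deliberately never invents risk from absent measurements.

The total count over all 13 factors drives the rule-based category:
0–3 suitable, 4–5 caution, ≥6 unsuitable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .errors import CodingError, ConfigurationError
from .records import MALE, SEXES, WorkerRecord

log = logging.getLogger(__name__)

#: Canonical factor names, in Tier 1 → Tier 3 order.
FACTOR_TIERS: dict[str, int] = {
    "obesity": 1,
    "hypertension": 1,
    "diabetes": 1,
    "dyslipidemia": 1,
    "elevated_liver_enzymes": 1,
    "abnormal_resting_hr": 1,
    "anemia": 1,
    "hearing_loss": 2,
    "abnormal_pulmonary": 2,
    "abnormal_ecg": 2,
    "low_fitness": 2,
    "significant_smoking": 3,
    "habitual_alcohol": 3,
}
FACTORS: tuple[str, ...] = tuple(FACTOR_TIERS)

MAX_TOTAL = len(FACTORS)  # 13


class FitnessCategory(str, Enum):
    """Ordered three-level fitness category from the total risk count."""

    SUITABLE = "suitable"
    CAUTION = "caution"
    UNSUITABLE = "unsuitable"

    @property
    def severity(self) -> int:
        return {"suitable": 0, "caution": 1, "unsuitable": 2}[self.value]


@dataclass(frozen=True)
class Vo2maxBand:
    """Half-open age band [age_min, age_max) with a lower normal bound."""

    age_min: float
    age_max: float
    lower_bound: float


@dataclass
class Vo2maxReference:
    """Sex- and age-specific lower bounds of normal VO₂max (mL/kg/min)."""

    bands: dict[str, list[Vo2maxBand]]

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.bands or not self.bands[sex]:
                raise ConfigurationError(
                    f"vo2max reference has no bands for sex '{sex}'"
                )
            ordered = sorted(self.bands[sex], key=lambda b: b.age_min)
            for lo, hi in zip(ordered, ordered[1:]):
                if lo.age_max < hi.age_min:
                    raise ConfigurationError(
                        f"vo2max reference gap for {sex}: ages "
                        f"[{lo.age_max}, {hi.age_min}) are uncovered"
                    )
                if lo.age_max > hi.age_min:
                    raise ConfigurationError(
                        f"vo2max reference overlap for {sex}: bands "
                        f"[{lo.age_min}, {lo.age_max}) and "
                        f"[{hi.age_min}, {hi.age_max})"
                    )
            self.bands[sex] = ordered

    def lower_bound(self, sex: str, age: float) -> float:
        if sex not in self.bands:
            raise CodingError(f"unknown sex value: {sex!r}")
        for band in self.bands[sex]:
            if band.age_min <= age < band.age_max:
                return band.lower_bound
        covered = (self.bands[sex][0].age_min, self.bands[sex][-1].age_max)
        raise ConfigurationError(
            f"age {age} outside vo2max reference coverage "
            f"[{covered[0]}, {covered[1]}) for sex '{sex}'"
        )


@dataclass
class CutoffConfig:
    """Operational thresholds for the 13 risk factors.

    ``rules`` maps each factor name to its named thresholds (see the
    packaged ``cutoffs.yaml`` for keys and units); ``vo2max_reference``
    supplies the age/sex lower bounds used by the low-fitness factor.
    """

    rules: dict[str, dict[str, float]]
    vo2max_reference: Vo2maxReference

    def __post_init__(self) -> None:
        expected = set(FACTORS) - {"abnormal_ecg", "low_fitness"}
        missing = expected - set(self.rules)
        if missing:
            raise ConfigurationError(
                f"cutoff table missing factors: {sorted(missing)}"
            )
        for factor, entry in self.rules.items():
            for key, val in entry.items():
                if val is None or not (float("-inf") < float(val) < float("inf")):
                    raise ConfigurationError(
                        f"non-finite threshold {factor}.{key} = {val!r}"
                    )


def _load_packaged_yaml(name: str) -> dict:
    text = resources.files("cssi.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_vo2max_reference(source=None) -> Vo2maxReference:
    """Load a VO₂max reference table from YAML (packaged default if None)."""
    if source is None:
        raw = _load_packaged_yaml("vo2max_reference.yaml")
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    bands = {
        sex: [Vo2maxBand(float(b["age_min"]), float(b["age_max"]),
                         float(b["lower_bound"])) for b in entries]
        for sex, entries in raw.items()
    }
    return Vo2maxReference(bands)


def load_cutoffs(path=None, vo2max_reference: Optional[Vo2maxReference] = None
                 ) -> CutoffConfig:
    """Load a :class:`CutoffConfig` from YAML (packaged defaults if None)."""
    if path is None:
        raw = _load_packaged_yaml("cutoffs.yaml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if vo2max_reference is None:
        vo2max_reference = load_vo2max_reference()
    return CutoffConfig(rules=raw, vo2max_reference=vo2max_reference)


DEFAULT_CUTOFFS = load_cutoffs


@dataclass
class RiskProfile:
    """Coded 0/1 risk flags for one worker, with tier sums and category.

    ``flags`` values are 0, 1, or ``None`` (all constituents missing);
    missing flags contribute 0 to the sums.
    """

    worker_id: str
    flags: dict[str, Optional[int]]
    tier1_sum: int = field(init=False)
    tier2_sum: int = field(init=False)
    tier3_sum: int = field(init=False)
    total: int = field(init=False)
    category: FitnessCategory = field(init=False)

    def __post_init__(self) -> None:
        sums = {1: 0, 2: 0, 3: 0}
        for name, tier in FACTOR_TIERS.items():
            sums[tier] += self.flags.get(name) or 0
        self.tier1_sum, self.tier2_sum, self.tier3_sum = sums[1], sums[2], sums[3]
        self.total = sums[1] + sums[2] + sums[3]
        self.category = assign_category(self.total)


def assign_category(total: int) -> FitnessCategory:
    """Map a total risk count to suitable (0–3) / caution (4–5) / unsuitable (≥6)."""
    if total < 0:
        raise ValueError(f"total risk count must be non-negative, got {total}")
    if total <= 3:
        return FitnessCategory.SUITABLE
    if total <= 5:
        return FitnessCategory.CAUTION
    return FitnessCategory.UNSUITABLE


def vo2max_is_low(vo2max: Optional[float], sex: str, age: float,
                  reference: Vo2maxReference) -> Optional[int]:
    """1 iff measured VO₂max is strictly below the (sex, age) lower bound.

    A value exactly at the bound is normal. Missing vo2max returns ``None``.
    """
    bound = reference.lower_bound(sex, age)  # validates sex/age coverage
    if vo2max is None:
        return None
    return int(vo2max < bound)


def _disjunction(*conds: Optional[bool]) -> Optional[int]:
    """OR over constituents where None marks an absent measurement."""
    present = [c for c in conds if c is not None]
    if not present:
        return None
    return int(any(present))


def _cmp(value: Optional[float], op: str, threshold: float) -> Optional[bool]:
    if value is None:
        return None
    if op == "ge":
        return value >= threshold
    if op == "gt":
        return value > threshold
    if op == "lt":
        return value < threshold
    raise ValueError(op)


def code_risk_factors(record: WorkerRecord, config: CutoffConfig) -> RiskProfile:
    """Code the 13 dichotomous risk factors for one worker.

    Requires ``sex`` and ``age`` (sex-specific cutoffs and the VO₂max
    reference depend on them). ``fev1_fvc`` must be on the percent scale;
    a value in (0, 2] looks like a 0–1 ratio and is rejected.
    """
    if record.sex not in SEXES:
        raise CodingError(
            f"worker {record.id}: unknown sex value {record.sex!r} "
            f"(expected one of {SEXES})"
        )
    if record.age is None or record.age <= 0:
        raise CodingError(f"worker {record.id}: age must be present and > 0")
    if record.fev1_fvc is not None and 0 < record.fev1_fvc <= 2:
        raise CodingError(
            f"worker {record.id}: fev1_fvc={record.fev1_fvc} looks like a "
            "0-1 ratio; supply it on the percent (0-100) scale"
        )
    r, rules = record, config.rules
    male = r.sex == MALE

    ob = rules["obesity"]
    waist_thr = ob["waist_ge_male"] if male else ob["waist_ge_female"]
    ht = rules["hypertension"]
    dm = rules["diabetes"]
    dl = rules["dyslipidemia"]
    lv = rules["elevated_liver_enzymes"]
    hr = rules["abnormal_resting_hr"]
    an = rules["anemia"]
    hb_thr = an["hb_lt_male"] if male else an["hb_lt_female"]
    he = rules["hearing_loss"]
    pf = rules["abnormal_pulmonary"]
    sm = rules["significant_smoking"]
    al = rules["habitual_alcohol"]

    flags: dict[str, Optional[int]] = {
        "obesity": _disjunction(
            _cmp(r.bmi, "ge", ob["bmi_ge"]),
            _cmp(r.waist, "ge", waist_thr),
        ),
        "hypertension": _disjunction(
            _cmp(r.sbp, "ge", ht["sbp_ge"]),
            _cmp(r.dbp, "ge", ht["dbp_ge"]),
            r.on_antihypertensive,
        ),
        "diabetes": _disjunction(
            _cmp(r.fasting_glucose, "ge", dm["glucose_ge"]),
            _cmp(r.hba1c, "ge", dm["hba1c_ge"]),
            r.on_antidiabetic,
        ),
        "dyslipidemia": _disjunction(
            _cmp(r.ldl, "ge", dl["ldl_ge"]),
            _cmp(r.hdl, "lt", dl["hdl_lt"]),
            _cmp(r.total_chol, "ge", dl["total_chol_ge"]),
            r.on_lipid_lowering,
        ),
        "elevated_liver_enzymes": _disjunction(
            _cmp(r.ast, "gt", lv["ast_gt"]),
            _cmp(r.alt, "gt", lv["alt_gt"]),
            _cmp(r.ggtp, "gt", lv["ggtp_gt"]),
        ),
        "abnormal_resting_hr": _disjunction(
            _cmp(r.resting_hr, "lt", hr["hr_lt"]),
            _cmp(r.resting_hr, "gt", hr["hr_gt"]),
        ),
        "anemia": _disjunction(_cmp(r.hemoglobin, "lt", hb_thr)),
        "hearing_loss": _disjunction(_cmp(r.pta_0_5_4k, "gt", he["pta_gt"])),
        "abnormal_pulmonary": _disjunction(
            _cmp(r.fev1_fvc, "lt", pf["fev1_fvc_lt"]),
            _cmp(r.fev1_pred, "lt", pf["fev1_pred_lt"]),
        ),
        "abnormal_ecg": None if r.ecg_abnormal is None else int(r.ecg_abnormal),
        "low_fitness": vo2max_is_low(
            r.vo2max, r.sex, r.age, config.vo2max_reference
        ),
        "significant_smoking": _disjunction(
            _cmp(r.pack_years, "ge", sm["pack_years_ge"])
        ),
        "habitual_alcohol": _disjunction(
            _cmp(r.alcohol_per_week, "ge", al["times_per_week_ge"])
        ),
    }

    missing = [name for name, v in flags.items() if v is None]
    if missing:
        log.warning(
            "worker %s: flags %s have no measured constituents; counted as 0",
            record.id, missing,
        )
    return RiskProfile(worker_id=record.id, flags=flags)


def code_cohort(records: Sequence[WorkerRecord],
                config: Optional[CutoffConfig] = None) -> list[RiskProfile]:
    """Code every record in a cohort with one shared cutoff configuration."""
    if config is None:
        config = load_cutoffs()
    return [code_risk_factors(r, config) for r in records]
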