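"""Seeded synthetic worker cohorts for testing the CSSI pipeline end to end.

The worker cohort the index was developed on is not deposited, so this module
generates surrogate cohorts whose *marginal* distributions match the
published sex-stratified summary statistics (per-sex mean ± SD for each
continuous examination variable, the cohort's male fraction, and prevalences
for the binary inputs). The joint distribution is a Gaussian copula whose
correlation matrix is configurable — identity by default, since the source
tables report no correlation structure; :func:`realistic_correlation`
provides a clearly-labelled non-published preset (BMI–waist 0.8, SBP–DBP
0.7, total–LDL cholesterol 0.9, AST–ALT 0.7).

Marginal families are chosen per variable from its mean/SD and physiologic
bounds:

* SD = 0 → the constant mean (e.g. female pack-years, published as 0.0±0.0);
* near-symmetric variables (normal out-of-bounds mass ≤ 1%) → normal draws
  with per-entry rejection up to a resample cap, then clipping;
* strongly floor-pressed variables (liver enzymes, triglycerides,
  pack-years, alcohol frequency, …) → moment-matched gamma on
  ``value − floor``, which reproduces the published mean and SD *exactly*
  while keeping the support non-negative. A normal truncated at the floor
  cannot do both once SD/mean approaches 1, and these laboratory and
  exposure variables are right-skewed in real populations anyway.

All sampling is driven by a single :class:`numpy.random.Generator`, so a
fixed ``(params, n, seed)`` triple is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .records import BINARY_FIELDS, CONTINUOUS_FIELDS, FEMALE, MALE, WorkerRecord
from .risk import FACTORS, CutoffConfig, code_risk_factors, load_cutoffs

# Published per-sex mean/SD for each continuous variable: (male, female).
_TABLE_MARGINALS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age": ((44.5, 10.7), (44.0, 8.9)),
    "bmi": ((25.0, 2.9), (23.0, 3.2)),
    "waist": ((83.9, 8.1), (71.1, 8.9)),
    "sbp": ((123.8, 10.4), (116.7, 10.8)),
    "dbp": ((76.7, 9.0), (71.0, 8.8)),
    "resting_hr": ((64.6, 10.1), (67.1, 9.3)),
    "fasting_glucose": ((97.2, 8.7), (94.5, 14.1)),
    "hba1c": ((5.7, 0.4), (5.7, 0.5)),
    "total_chol": ((198.9, 36.7), (210.3, 29.5)),
    "ldl": ((119.4, 33.0), (127.9, 28.9)),
    "hdl": ((54.7, 15.6), (63.9, 14.2)),
    "triglycerides": ((150.0, 103.8), (109.9, 55.5)),
    "ast": ((27.6, 16.0), (21.7, 10.0)),
    "alt": ((35.0, 32.8), (20.7, 13.8)),
    "ggtp": ((33.4, 23.2), (15.2, 10.9)),
    "hemoglobin": ((15.6, 1.0), (13.3, 1.0)),
    "pta_0_5_4k": ((15.1, 9.1), (11.5, 4.6)),
    "fev1_fvc": ((84.4, 6.4), (83.3, 5.0)),
    "fev1_pred": ((88.0, 9.2), (88.2, 7.8)),
    "vo2max": ((34.5, 5.3), (28.8, 3.6)),
    "pack_years": ((7.8, 11.2), (0.0, 0.0)),
    "alcohol_per_week": ((1.3, 1.2), (0.3, 0.7)),
}

# Physiologic (floor, ceiling) per variable.
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    **{v: (0.0, np.inf) for v in CONTINUOUS_FIELDS},
    "age": (18.0, 120.0),
    "fev1_fvc": (0.0, 100.0),
}

# ECG prevalences follow the published per-sex fractions; medication-use
# prevalences are not published and are plausible working-age defaults.
_DEFAULT_PREVALENCES: dict[str, Union[float, dict[str, float]]] = {
    "on_antihypertensive": 0.08,
    "on_antidiabetic": 0.02,
    "on_lipid_lowering": 0.04,
    "ecg_abnormal": {MALE: 11 / 72, FEMALE: 4 / 39},
}

_NORMAL_MASS_TOL = 0.01   # switch marginal family above this clipped mass
_REJECTION_ROUNDS = 20    # per-entry redraw cap before clipping


def default_marginals() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        var: {MALE: m, FEMALE: f} for var, (m, f) in _TABLE_MARGINALS.items()
    }


@dataclass
class CohortParams:
    """Generator configuration; defaults reproduce the published summary table.

    ``marginals[var][sex] = (mean, sd)`` in the variable's clinical units.
    ``prevalences`` entries are either a scalar in [0,1] or a per-sex dict.
    ``correlation`` is a symmetric PSD matrix with unit diagonal over
    ``CONTINUOUS_FIELDS`` order (None = identity). ``missing_rate`` injects
    completely-at-random missingness into continuous fields.
    """

    marginals: dict[str, dict[str, tuple[float, float]]] = dc_field(
        default_factory=default_marginals
    )
    sex_fraction_male: float = 72 / 111
    prevalences: dict[str, Union[float, dict[str, float]]] = dc_field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )
    correlation: Optional[np.ndarray] = None
    bounds: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    missing_rate: float = 0.0

    def validate(self) -> None:
        for var in CONTINUOUS_FIELDS:
            if var not in self.marginals:
                raise ConfigurationError(f"marginals missing variable '{var}'")
            for sex in (MALE, FEMALE):
                mean, sd = self.marginals[var][sex]
                if sd < 0:
                    raise ConfigurationError(
                        f"marginals[{var}][{sex}]: sd {sd} < 0"
                    )
                lo, hi = self.bounds.get(var, (-np.inf, np.inf))
                if not lo <= mean <= hi:
                    raise ConfigurationError(
                        f"marginals[{var}][{sex}]: mean {mean} outside "
                        f"bounds [{lo}, {hi}]"
                    )
        if not 0 <= self.sex_fraction_male <= 1:
            raise ConfigurationError(
                f"sex_fraction_male {self.sex_fraction_male} not in [0,1]"
            )
        for name, p in self.prevalences.items():
            vals = p.values() if isinstance(p, dict) else [p]
            for v in vals:
                if not 0 <= v <= 1:
                    raise ConfigurationError(
                        f"prevalence '{name}' = {v} not in [0,1]"
                    )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError(
                f"missing_rate {self.missing_rate} not in [0,1)"
            )
        if self.correlation is not None:
            _validate_correlation(np.asarray(self.correlation, float))

    def prevalence(self, name: str, sex: str) -> float:
        p = self.prevalences.get(name, 0.0)
        return p[sex] if isinstance(p, dict) else p


def _validate_correlation(corr: np.ndarray) -> None:
    p = len(CONTINUOUS_FIELDS)
    if corr.shape != (p, p):
        raise ConfigurationError(
            f"correlation matrix shape {corr.shape} != ({p}, {p}) over "
            f"{p} continuous variables"
        )
    for i in range(p):
        if not np.isclose(corr[i, i], 1.0):
            raise ConfigurationError(
                f"correlation diagonal entry ({CONTINUOUS_FIELDS[i]},"
                f"{CONTINUOUS_FIELDS[i]}) = {corr[i, i]} != 1"
            )
    asym = np.argwhere(~np.isclose(corr, corr.T))
    if asym.size:
        i, j = asym[0]
        raise ConfigurationError(
            f"correlation matrix asymmetric at "
            f"({CONTINUOUS_FIELDS[i]}, {CONTINUOUS_FIELDS[j]}): "
            f"{corr[i, j]} vs {corr[j, i]}"
        )
    bad = np.argwhere(np.abs(corr) > 1 + 1e-12)
    if bad.size:
        i, j = bad[0]
        raise ConfigurationError(
            f"correlation entry ({CONTINUOUS_FIELDS[i]}, "
            f"{CONTINUOUS_FIELDS[j]}) = {corr[i, j]} outside [-1, 1]"
        )
    min_eig = float(np.linalg.eigvalsh(corr).min())
    if min_eig < -1e-8:
        raise ConfigurationError(
            f"correlation matrix not positive semi-definite "
            f"(min eigenvalue {min_eig:.3g})"
        )


def realistic_correlation() -> np.ndarray:
    """A plausibility preset, NOT taken from any published source (the
    summary tables report no correlations): BMI–waist 0.8, SBP–DBP 0.7,
    total_chol–LDL 0.9, AST–ALT 0.7; all other pairs independent."""
    idx = {v: i for i, v in enumerate(CONTINUOUS_FIELDS)}
    corr = np.eye(len(CONTINUOUS_FIELDS))
    for a, b, r in [
        ("bmi", "waist", 0.8),
        ("sbp", "dbp", 0.7),
        ("total_chol", "ldl", 0.9),
        ("ast", "alt", 0.7),
    ]:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr


def _sample_marginal(z: np.ndarray, mean: float, sd: float,
                     lo: float, hi: float, rng: np.random.Generator
                     ) -> np.ndarray:
    """Map standard-normal copula draws onto one variable's marginal."""
    if sd == 0:
        return np.full(z.shape, mean)
    p_out = stats.norm.cdf(lo, mean, sd) + stats.norm.sf(hi, mean, sd)
    if p_out <= _NORMAL_MASS_TOL:
        x = mean + sd * z
        # per-entry rejection keeps the marginal near-exact; the final clip
        # only touches the <=1% tail that survives all redraw rounds
        for _ in range(_REJECTION_ROUNDS):
            bad = (x < lo) | (x > hi)
            if not bad.any():
                break
            x[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
        return np.clip(x, lo, hi)
    if not np.isfinite(lo) or mean <= lo:
        raise ConfigurationError(
            f"cannot build a skewed marginal with mean {mean} at or below "
            f"its floor {lo}"
        )
    shape = (mean - lo) ** 2 / sd**2
    scale = sd**2 / (mean - lo)
    x = lo + stats.gamma.ppf(stats.norm.cdf(z), shape, scale=scale)
    return np.clip(x, lo, hi)


def generate_cohort(params: CohortParams, n: int, seed: int
                    ) -> list[WorkerRecord]:
    """Draw ``n`` synthetic workers; identical inputs give identical output."""
    if n < 0:
        raise ValueError(f"cohort size must be non-negative, got {n}")
    params.validate()
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(n) < params.sex_fraction_male, MALE, FEMALE)

    p = len(CONTINUOUS_FIELDS)
    corr = (np.eye(p) if params.correlation is None
            else np.asarray(params.correlation, float))
    # PSD with possible zero eigenvalues: Cholesky of corr + tiny jitter
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))

    values = np.empty((n, p))
    for sex in (MALE, FEMALE):
        mask = sexes == sex
        m = int(mask.sum())
        z = rng.standard_normal((m, p)) @ chol.T
        cols = np.empty((m, p))
        for j, var in enumerate(CONTINUOUS_FIELDS):
            mean, sd = params.marginals[var][sex]
            lo, hi = params.bounds.get(var, (-np.inf, np.inf))
            cols[:, j] = _sample_marginal(z[:, j], mean, sd, lo, hi, rng)
        values[mask] = cols

    flags = {}
    for name in BINARY_FIELDS:
        u = rng.random(n)
        thresh = np.array([params.prevalence(name, s) for s in sexes])
        flags[name] = u < thresh

    miss = None
    if params.missing_rate > 0:
        # demographics stay complete: coding needs age for the VO2max bands
        miss = rng.random((n, p)) < params.missing_rate
        miss[:, CONTINUOUS_FIELDS.index("age")] = False

    records = []
    for i in range(n):
        kw = {}
        for j, var in enumerate(CONTINUOUS_FIELDS):
            kw[var] = None if (miss is not None and miss[i, j]) \
                else float(values[i, j])
        for name in BINARY_FIELDS:
            kw[name] = bool(flags[name][i])
        records.append(
            WorkerRecord(id=f"W{i:05d}", sex=str(sexes[i]), **kw)
        )
    return records


def plant_outcome(cohort: Sequence[WorkerRecord],
                  true_weights: Mapping[str, float],
                  intercept: float, seed: int,
                  cutoffs: Optional[CutoffConfig] = None) -> np.ndarray:
    """Draw Bernoulli labels from a logistic model on the coded risk flags.

    ``P(y=1) = logistic(intercept + Σ w_f · flag_f)`` with flags computed by
    the default cutoff rules (missing flags contribute 0). This gives the
    weighting stage a known ground truth for parameter-recovery tests.
    """
    unknown = set(true_weights) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown risk-factor names: {sorted(unknown)}")
    if cutoffs is None:
        cutoffs = load_cutoffs()
    rng = np.random.default_rng(seed)
    eta = np.full(len(cohort), float(intercept))
    for i, rec in enumerate(cohort):
        profile = code_risk_factors(rec, cutoffs)
        eta[i] += sum(
            w * (profile.flags[f] or 0) for f, w in true_weights.items()
        )
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(cohort)) < prob).astype(int)
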