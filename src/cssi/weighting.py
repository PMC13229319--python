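"""Additive CSSI weights from L1-penalized logistic regression, and scoring.

The outcome is the rule-based *unsuitable* label (total risk count ≥ 6,
coded 1) against suitable/caution (0). Predictors are the 13 dichotomous
risk flags; age and sex enter as covariates but never receive a score
weight. Columns are mean-imputed and z-scored (training rows only; the
fitted transform is reused for held-out rows), then an L1-penalized
logistic model is fit with an unpenalized intercept.

The penalty is parameterised on the lasso scale

    (1/n) · Σ deviance_i + λ · ‖β‖₁

so ``λ`` maps onto scikit-learn's ``C = 1/(n·λ)``. ``λ="auto"`` picks the
grid value minimising seeded stratified k-fold cross-validated deviance.

Weights: raw factor coefficients are truncated at zero (a negative
coefficient would read as protective, which a screening index must not
encode) and the positive part is normalized to sum to 1. A worker's raw
score is Σ flag·weight ∈ [0,1]; the CSSI score is 100× that. Note the
deliberate scale mismatch, kept for fidelity to the published construction:
coefficients are estimated on z-scored predictors but applied to raw 0/1
flags, so weights inherit a dependence on factor prevalence.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import FittingError
from .records import WorkerRecord
from .risk import FACTORS, FitnessCategory, RiskProfile

log = logging.getLogger(__name__)

COVARIATES = ("age", "sex_male")
DESIGN_COLUMNS = FACTORS + COVARIATES


@dataclass(frozen=True)
class FitSpec:
    """Configuration of the weighting fit.

    ``penalty_lambda`` is a positive float on the lasso scale or "auto"
    (stratified CV over ``n_lambda`` log-spaced values spanning
    ``lambda_min_ratio``·λ_max … λ_max). ``seed`` drives CV fold shuffling
    and the solver.
    """

    penalty_lambda: Union[float, str] = "auto"
    standardize: bool = True
    impute: str = "mean"
    seed: int = 0
    cv_folds: int = 5
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-2
    max_iter: int = 20000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.penalty_lambda != "auto" and not self.penalty_lambda > 0:
            raise ValueError("penalty_lambda must be positive or 'auto'")
        if self.impute != "mean":
            raise ValueError("only mean imputation is supported")

    def fingerprint(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def build_design(profiles: Sequence[RiskProfile],
                 records: Sequence[WorkerRecord]
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the model frame (13 flags + age + sex_male) and outcome.

    Missing flags and measurements become NaN for the imputation step.
    The outcome is 1 iff the rule-based category is unsuitable.
    """
    if len(profiles) != len(records):
        raise ValueError("profiles and records must be aligned 1:1")
    by_id = {r.id: r for r in records}
    rows, y = [], []
    for prof in profiles:
        rec = by_id.get(prof.worker_id)
        if rec is None:
            raise ValueError(f"no record for worker {prof.worker_id}")
        row = {f: (np.nan if prof.flags[f] is None else float(prof.flags[f]))
               for f in FACTORS}
        row["age"] = np.nan if rec.age is None else float(rec.age)
        row["sex_male"] = np.nan if rec.sex is None else float(rec.sex == "male")
        rows.append(row)
        y.append(int(prof.category is FitnessCategory.UNSUITABLE))
    X = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS),
                     index=[p.worker_id for p in profiles])
    return X, np.asarray(y)


@dataclass
class Preprocessor:
    """Mean imputation + z-scoring, parameterised on training rows only.

    Zero-variance training columns get divisor 1, so they standardize to
    all-zeros instead of NaN.
    """

    columns: tuple[str, ...] = ()
    impute_means: Optional[pd.Series] = None
    centers: Optional[pd.Series] = None
    scales: Optional[pd.Series] = None

    def fit(self, X: pd.DataFrame) -> "Preprocessor":
        if X.shape[1] == 0:
            raise ValueError("empty predictor set")
        if len(X) < 2:
            raise ValueError("need at least 2 rows to preprocess")
        self.columns = tuple(X.columns)
        means = X.mean(axis=0)
        # a column that is entirely missing imputes to 0
        self.impute_means = means.fillna(0.0)
        filled = X.fillna(self.impute_means)
        self.centers = filled.mean(axis=0)
        sd = filled.std(axis=0, ddof=0)
        self.scales = sd.where(sd > 0, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if self.impute_means is None:
            raise RuntimeError("Preprocessor not fitted")
        X = X[list(self.columns)]
        filled = X.fillna(self.impute_means)
        return ((filled - self.centers) / self.scales).to_numpy(float)

    def fit_transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X).transform(X)


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int,
                min_ratio: float) -> np.ndarray:
    """Descending log-spaced λ grid from the smallest all-zero λ."""
    n = len(y)
    lam_max = float(np.abs(X.T @ (y - y.mean())).max()) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _make_model(n: int, lam: float, spec: FitSpec) -> LogisticRegression:
    # pure-L1 elastic net; saga leaves the intercept unpenalized
    return LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="saga",
        max_iter=spec.max_iter, tol=spec.tol, random_state=spec.seed,
        warm_start=True,
    )


def _checked_fit(model: LogisticRegression, X: np.ndarray, y: np.ndarray,
                 lam: float, spec: FitSpec) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning as exc:
            raise FittingError(
                f"L1 logistic fit did not converge at lambda={lam:.4g} "
                f"within {spec.max_iter} iterations (n={len(y)}); "
                "increase max_iter or the penalty"
            ) from exc


def _fit_at_lambda(X: np.ndarray, y: np.ndarray, lam: float, spec: FitSpec
                   ) -> tuple[np.ndarray, float]:
    model = _make_model(len(y), lam, spec)
    _checked_fit(model, X, y, lam, spec)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def _fit_path(X: np.ndarray, y: np.ndarray, grid: np.ndarray, spec: FitSpec
              ) -> list[tuple[np.ndarray, float]]:
    """Fit a descending λ path with warm starts (one solver instance)."""
    n = len(y)
    model = _make_model(n, float(grid[0]), spec)
    out = []
    for lam in grid:
        model.C = 1.0 / (n * float(lam))
        _checked_fit(model, X, y, float(lam), spec)
        out.append((model.coef_.ravel().copy(), float(model.intercept_[0])))
    return out


def _deviance(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def select_lambda(X: np.ndarray, y: np.ndarray, spec: FitSpec) -> float:
    """Pick λ by seeded stratified k-fold CV deviance (ties → larger λ)."""
    grid = lambda_grid(X, y, spec.n_lambda, spec.lambda_min_ratio)
    minority = int(min(np.sum(y == 1), np.sum(y == 0)))
    k = min(spec.cv_folds, minority)
    if k < 2:
        raise FittingError(
            f"cannot cross-validate lambda with only {minority} "
            "minority-class observations; supply a fixed lambda or a "
            "larger sample"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    dev = np.zeros(len(grid))
    for tr, te in skf.split(X, y):
        for g, (coef, b0) in enumerate(_fit_path(X[tr], y[tr], grid, spec)):
            dev[g] += _deviance(expit(b0 + X[te] @ coef), y[te])
    # grid is descending, argmin returns the first (largest) λ among ties
    return float(grid[int(np.argmin(dev))])


def fit_l1_logistic(X: np.ndarray, y: np.ndarray,
                    spec: FitSpec) -> "FittedModel":
    """L1-penalized logistic fit on a preprocessed design matrix."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise FittingError(
            "outcome has a single class; the unsuitable label needs both "
            "classes — use a larger or less homogeneous sample"
        )
    lam = (select_lambda(X, y, spec)
           if spec.penalty_lambda == "auto" else float(spec.penalty_lambda))
    coef, intercept = _fit_at_lambda(X, y, lam, spec)
    return FittedModel(coefficients=coef, intercept=intercept,
                       penalty_lambda=lam, columns=tuple(DESIGN_COLUMNS))


@dataclass
class FittedModel:
    """Coefficients of one penalized fit, on the standardized scale."""

    coefficients: np.ndarray
    intercept: float
    penalty_lambda: float
    columns: tuple[str, ...]

    def coef_by_name(self) -> dict[str, float]:
        return dict(zip(self.columns, map(float, self.coefficients)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + X @ self.coefficients)

    def factor_coefficients(self) -> dict[str, float]:
        named = self.coef_by_name()
        return {f: named[f] for f in FACTORS if f in named}


@dataclass
class WeightSet:
    """Raw, truncated, and normalized additive weights per factor.

    Normalized weights are non-negative and sum to 1 unless every raw
    coefficient is ≤ 0, in which case the set is *degenerate* (all zeros).
    """

    factors: tuple[str, ...]
    raw: dict[str, float]
    truncated: dict[str, float]
    normalized: dict[str, float]
    degenerate: bool
    provenance: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": list(self.factors),
            "raw_coefficient": [self.raw[f] for f in self.factors],
            "truncated_coefficient": [self.truncated[f] for f in self.factors],
            "normalized_weight": [self.normalized[f] for f in self.factors],
        })


def derive_weights(raw: Union[Mapping[str, float], Sequence[float]],
                   factors: Optional[Sequence[str]] = None,
                   provenance: str = "") -> WeightSet:
    """Truncate raw coefficients at 0 and normalize the positives to sum 1.

    ``raw`` may be a mapping over (a subset of) the 13 factor names —
    absent factors get raw coefficient 0 — or a plain sequence, in which
    case ``factors`` supplies the names (defaulting to the canonical 13,
    requiring a full-length vector).
    """
    if isinstance(raw, Mapping):
        unknown = set(raw) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown risk-factor names: {sorted(unknown)}")
        names = tuple(FACTORS)
        values = {f: float(raw.get(f, 0.0)) for f in names}
    else:
        vals = [float(v) for v in raw]
        if factors is None:
            if len(vals) != len(FACTORS):
                raise ValueError(
                    f"expected {len(FACTORS)} coefficients for the canonical "
                    f"factor set, got {len(vals)}; pass `factors` for a "
                    "partial vector"
                )
            names = tuple(FACTORS)
        else:
            if len(vals) != len(factors):
                raise ValueError(
                    f"coefficient vector length {len(vals)} != "
                    f"{len(factors)} factor names"
                )
            names = tuple(factors)
        values = dict(zip(names, vals))

    truncated = {f: max(v, 0.0) for f, v in values.items()}
    total = sum(truncated.values())
    if total > 0:
        normalized = {f: v / total for f, v in truncated.items()}
        degenerate = False
    else:
        normalized = {f: 0.0 for f in names}
        degenerate = True
        log.warning(
            "all raw coefficients are non-positive; emitting a degenerate "
            "all-zero weight set — scores will be identically 0"
        )
    return WeightSet(factors=names, raw=values, truncated=truncated,
                     normalized=normalized, degenerate=degenerate,
                     provenance=provenance)


@dataclass
class ScoreResult:
    """Additive score for one worker: raw ∈ [0,1], CSSI = 100·raw."""

    worker_id: str
    raw_score: float
    cssi_score: float
    category: FitnessCategory


def compute_score(profile: RiskProfile, weights: WeightSet) -> ScoreResult:
    """Σ flag·normalized_weight, scaled to 0–100; missing flags add 0."""
    raw = sum(
        weights.normalized.get(f, 0.0) * (profile.flags.get(f) or 0)
        for f in weights.factors
    )
    return ScoreResult(
        worker_id=profile.worker_id,
        raw_score=raw,
        cssi_score=100.0 * raw,
        category=profile.category,
    )


def fit_weights(profiles: Sequence[RiskProfile],
                records: Sequence[WorkerRecord],
                spec: FitSpec = FitSpec(),
                ) -> tuple[WeightSet, FittedModel, Preprocessor]:
    """End-to-end weighting stage: design → preprocess → L1 fit → weights."""
    X, y = build_design(profiles, records)
    pre = Preprocessor().fit(X)
    model = fit_l1_logistic(pre.transform(X), y, spec)
    weights = derive_weights(
        model.factor_coefficients(),
        provenance=f"fitspec:{spec.fingerprint()};lambda:{model.penalty_lambda:.6g}",
    )
    return weights, model, pre
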