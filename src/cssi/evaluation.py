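"""Internal validation: LOOCV discrimination, confusion-matrix metrics,
ranking metrics, and bootstrap selection-frequency stability.

Leave-one-out cross-validation re-runs the *entire* weighting pipeline —
imputation means, z-score parameters, λ selection, and the penalized fit —
on each n−1 training set, so no statistic of the held-out worker leaks into
their predicted probability. The pooled out-of-fold probabilities yield
AUROC (midrank Mann–Whitney), AUPRC (step-wise average precision, ties
grouped), and a confusion matrix thresholded at probability ≥ 0.50 on the
model scale.

Degenerate metric ratios (0/0) return ``None`` explicitly rather than NaN.
Reported values are rounded half-up to 3 decimals for display only; full
precision is retained in the report object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import StabilityError
from .records import WorkerRecord
from .risk import FACTORS, RiskProfile
from .weighting import FitSpec, Preprocessor, build_design, fit_l1_logistic

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "balanced_accuracy", "sensitivity",
                "specificity", "ppv", "npv", "f1")


def round_half_up(x: Optional[float], ndigits: int = 3) -> Optional[float]:
    """Decimal half-up rounding for report display (1.0005 → 1.001)."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 classification counts at a fixed probability threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"confusion count {name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Full metric set from counts; 0/0 ratios are ``None``, not NaN."""
    if c.n == 0:
        raise ValueError("confusion matrix is empty")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    balanced = None if sens is None or spec is None else (sens + spec) / 2
    return {
        "accuracy": (c.tp + c.tn) / c.n,
        "balanced_accuracy": balanced,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "f1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def confusion_at_threshold(probs: Sequence[float], labels: Sequence[int],
                           threshold: float = 0.5) -> ConfusionCounts:
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    pred = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def auroc(probs: Sequence[float], labels: Sequence[int]) -> Optional[float]:
    """Mann–Whitney AUROC with midrank tie handling.

    Equals P(score⁺ > score⁻) + ½·P(score⁺ = score⁻) over all
    positive/negative pairs. ``None`` when one class is absent.
    """
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(p)  # midranks
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(probs: Sequence[float], labels: Sequence[int]) -> Optional[float]:
    """Average precision: Σ precision(t)·Δrecall(t) over descending
    probability thresholds, with tied probabilities grouped as one step.
    ``None`` when there are no positives."""
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        return None
    order = np.argsort(-p, kind="stable")
    p, y = p[order], y[order]
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(p)
    while i < n:
        j = i
        while j < n and p[j] == p[i]:  # one step per distinct probability
            j += 1
        tp += int(np.sum(y[i:j] == 1))
        fp += int(np.sum(y[i:j] == 0))
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return float(ap)


@dataclass
class ValidationReport:
    """Pooled out-of-fold validation summary."""

    n: int
    positives: int
    auroc: Optional[float]
    auprc: Optional[float]
    threshold: float
    counts: ConfusionCounts
    metrics: dict[str, Optional[float]]
    probabilities: np.ndarray
    labels: np.ndarray
    worker_ids: list[str]
    degenerate_folds: int = 0

    def rounded(self, ndigits: int = 3) -> dict[str, Optional[float]]:
        out = {"auroc": round_half_up(self.auroc, ndigits),
               "auprc": round_half_up(self.auprc, ndigits)}
        out.update({k: round_half_up(v, ndigits)
                    for k, v in self.metrics.items()})
        return out


def loocv(profiles: Sequence[RiskProfile], records: Sequence[WorkerRecord],
          spec: FitSpec = FitSpec(), threshold: float = 0.5,
          refit_per_fold: bool = True,
          outcome: Optional[Sequence[int]] = None) -> ValidationReport:
    """Leave-one-out validation of the unsuitable classifier.

    ``refit_per_fold=True`` (default) re-runs preprocessing, λ selection and
    the fit on every n−1 subset — the leakage-free reading. With ``False``
    one full-sample model scores each held-out worker instead (the
    fixed-weights variant, for comparison only). ``outcome`` overrides the
    rule-derived unsuitable label, e.g. with planted synthetic labels.
    """
    X, y = build_design(profiles, records)
    if outcome is not None:
        y = np.asarray(outcome, int)
    n = len(y)
    if n < 10:
        raise ValueError(f"LOOCV needs at least 10 workers, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; LOOCV is undefined")

    probs = np.empty(n)
    degenerate = 0
    if not refit_per_fold:
        pre = Preprocessor().fit(X)
        model = fit_l1_logistic(pre.transform(X), y, spec)
        probs[:] = model.predict_proba(pre.transform(X))
    else:
        mask = np.ones(n, bool)
        for i in range(n):
            mask[i] = False
            X_tr, y_tr = X.iloc[mask], y[mask]
            if len(np.unique(y_tr)) < 2:
                probs[i] = float(y_tr.mean())
                degenerate += 1
                log.warning(
                    "fold %d: single-class training outcome; using training "
                    "prevalence %.3f as the held-out probability", i, probs[i]
                )
            else:
                pre = Preprocessor().fit(X_tr)
                model = fit_l1_logistic(pre.transform(X_tr), y_tr, spec)
                probs[i] = float(
                    model.predict_proba(pre.transform(X.iloc[[i]]))[0]
                )
            mask[i] = True

    counts = confusion_at_threshold(probs, y, threshold)
    return ValidationReport(
        n=n,
        positives=int(y.sum()),
        auroc=auroc(probs, y),
        auprc=auprc(probs, y),
        threshold=threshold,
        counts=counts,
        metrics=confusion_metrics(counts),
        probabilities=probs,
        labels=y,
        worker_ids=[p.worker_id for p in profiles],
        degenerate_folds=degenerate,
    )


@dataclass
class StabilityReport:
    """Per-factor selection frequency over B bootstrap refits."""

    B: int
    selection_frequency: dict[str, float]
    mean_truncated_coefficient: dict[str, float]
    master_seed: int
    redraws: int = 0
    selection_rule: str = "positive"

    def as_rows(self) -> list[dict]:
        return [
            {
                "factor": f,
                "selection_frequency": self.selection_frequency[f],
                "mean_truncated_coefficient":
                    self.mean_truncated_coefficient[f],
            }
            for f in FACTORS
        ]


def bootstrap_stability(profiles: Sequence[RiskProfile],
                        records: Sequence[WorkerRecord],
                        spec: FitSpec = FitSpec(),
                        B: int = 1000, master_seed: int = 0,
                        selection: str = "positive",
                        min_positives: int = 2,
                        max_redraw: int = 100,
                        outcome: Optional[Sequence[int]] = None
                        ) -> StabilityReport:
    """Refit the weighting pipeline on B resamples drawn with replacement.

    A factor counts as *selected* in a resample when its raw coefficient is
    strictly positive (``selection="positive"``, mirroring the positive-
    weight rule) or merely nonzero (``selection="nonzero"``). Resamples with
    fewer than ``min_positives`` unsuitable workers are redrawn, up to
    ``max_redraw`` consecutive attempts each.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if selection not in ("positive", "nonzero"):
        raise ValueError(f"unknown selection rule {selection!r}")
    X, y = build_design(profiles, records)
    if outcome is not None:
        y = np.asarray(outcome, int)
    n = len(y)
    rng = np.random.default_rng(master_seed)

    selected = {f: 0 for f in FACTORS}
    coef_sum = {f: 0.0 for f in FACTORS}
    redraws = 0
    for b in range(B):
        for attempt in range(max_redraw + 1):
            idx = rng.integers(0, n, size=n)
            y_b = y[idx]
            if y_b.sum() >= min_positives and (1 - y_b).sum() >= 1:
                break
            redraws += 1
        else:
            raise StabilityError(
                f"resample {b}: could not draw >= {min_positives} positive "
                f"outcomes in {max_redraw} attempts; the cohort has too few "
                "unsuitable workers for a stable bootstrap"
            )
        X_b = X.iloc[idx]
        pre = Preprocessor().fit(X_b)
        model = fit_l1_logistic(pre.transform(X_b), y_b, spec)
        for f, c in model.factor_coefficients().items():
            hit = c > 0 if selection == "positive" else c != 0
            selected[f] += int(hit)
            coef_sum[f] += max(c, 0.0)

    return StabilityReport(
        B=B,
        selection_frequency={f: selected[f] / B for f in FACTORS},
        mean_truncated_coefficient={f: coef_sum[f] / B for f in FACTORS},
        master_seed=master_seed,
        redraws=redraws,
        selection_rule=selection,
    )
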