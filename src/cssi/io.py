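"""File formats, run configuration, and the end-to-end pipeline.

Interchange formats are deliberately plain: cohorts, risk profiles, scores
and stability tables as CSV with fixed case-sensitive headers ("NA" or an
empty cell = missing); weights and the validation report as JSON; cutoff
and VO₂max reference tables as YAML so guideline overrides are data, not
code. Report JSON carries both display-rounded values and full-precision
``*_raw`` fields. Every stochastic stage records its seed in the run
manifest, and re-running an identical configuration reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortParams, generate_cohort
from .errors import SchemaError
from .evaluation import (
    StabilityReport,
    ValidationReport,
    bootstrap_stability,
    loocv,
)
from .records import (
    ALL_FIELDS,
    BINARY_FIELDS,
    CONTINUOUS_FIELDS,
    SEXES,
    WorkerRecord,
)
from .risk import (
    FACTORS,
    CutoffConfig,
    RiskProfile,
    code_cohort,
    load_cutoffs,
    load_vo2max_reference,
)
from .weighting import FitSpec, ScoreResult, WeightSet, compute_score, fit_weights

log = logging.getLogger(__name__)

COHORT_COLUMNS: tuple[str, ...] = tuple(ALL_FIELDS)
PROFILE_COLUMNS: tuple[str, ...] = (
    ("id",) + FACTORS + ("tier1_sum", "tier2_sum", "tier3_sum", "total",
                         "category")
)

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort_csv(records: Sequence[WorkerRecord], path) -> None:
    """Write a cohort CSV to a path or text file-like object."""

    def _emit(fh) -> None:
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for rec in records:
            fh.write(",".join(_fmt(rec.get(c)) for c in COHORT_COLUMNS) + "\n")

    if hasattr(path, "write"):
        _emit(path)
    else:
        with open(path, "w", newline="") as fh:
            _emit(fh)


def _check_header(found: Sequence[str], expected: Sequence[str],
                  what: str) -> None:
    missing = [c for c in expected if c not in found]
    extra = [c for c in found if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise SchemaError(f"{what} header invalid: " + "; ".join(parts))


def read_cohort_csv(path) -> list[WorkerRecord]:
    """Read a cohort CSV; "NA" and empty cells parse as missing, never 0."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df.columns, COHORT_COLUMNS, "cohort CSV")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        kw: dict = {"id": row["id"]}
        sex = row["sex"]
        if sex in ("", "NA"):
            kw["sex"] = None
        elif sex not in SEXES:
            raise SchemaError(
                f"cohort CSV line {i}: unknown sex token {sex!r}"
            )
        else:
            kw["sex"] = sex
        for col in CONTINUOUS_FIELDS:
            cell = row[col]
            if cell in ("", "NA"):
                kw[col] = None
                continue
            try:
                kw[col] = float(cell)
            except ValueError as exc:
                raise SchemaError(
                    f"cohort CSV line {i}, column '{col}': "
                    f"unparseable numeric {cell!r}"
                ) from exc
        for col in BINARY_FIELDS:
            cell = row[col]
            if cell in ("", "NA"):
                kw[col] = None
            elif cell in _TRUE:
                kw[col] = True
            elif cell in _FALSE:
                kw[col] = False
            else:
                raise SchemaError(
                    f"cohort CSV line {i}, column '{col}': "
                    f"unparseable boolean {cell!r}"
                )
        records.append(WorkerRecord(**kw))
    return records


def write_profiles_csv(profiles: Sequence[RiskProfile], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            cells = [p.worker_id]
            cells += [_fmt(p.flags[f]) for f in FACTORS]
            cells += [str(p.tier1_sum), str(p.tier2_sum), str(p.tier3_sum),
                      str(p.total), p.category.value]
            fh.write(",".join(cells) + "\n")


def read_profiles_csv(path) -> list[RiskProfile]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df.columns, PROFILE_COLUMNS, "profiles CSV")
    profiles = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        flags = {}
        for f in FACTORS:
            cell = row[f]
            if cell in ("", "NA"):
                flags[f] = None
            elif cell in ("0", "1"):
                flags[f] = int(cell)
            else:
                raise SchemaError(
                    f"profiles CSV line {i}, column '{f}': "
                    f"flag must be 0/1/NA, got {cell!r}"
                )
        profiles.append(RiskProfile(worker_id=row["id"], flags=flags))
    return profiles


def write_scores_csv(scores: Sequence[ScoreResult], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("id,raw_score,cssi_score,category\n")
        for s in scores:
            fh.write(f"{s.worker_id},{s.raw_score!r},{s.cssi_score!r},"
                     f"{s.category.value}\n")


def write_weights_json(weights: WeightSet, path) -> None:
    payload = {
        "factors": list(weights.factors),
        "raw_coefficients": weights.raw,
        "truncated_coefficients": weights.truncated,
        "normalized_weights": weights.normalized,
        "degenerate": weights.degenerate,
        "provenance": weights.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_weights_json(path) -> WeightSet:
    with open(path) as fh:
        d = json.load(fh)
    return WeightSet(
        factors=tuple(d["factors"]),
        raw=d["raw_coefficients"],
        truncated=d["truncated_coefficients"],
        normalized=d["normalized_weights"],
        degenerate=d["degenerate"],
        provenance=d.get("provenance", ""),
    )


def write_report_json(report: ValidationReport, path, ndigits: int = 3) -> None:
    payload = {
        "n": report.n,
        "positives": report.positives,
        "threshold": report.threshold,
        "degenerate_folds": report.degenerate_folds,
        "counts": dataclasses.asdict(report.counts),
        **report.rounded(ndigits),
        "auroc_raw": report.auroc,
        "auprc_raw": report.auprc,
        **{f"{k}_raw": v for k, v in report.metrics.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_oof_csv(report: ValidationReport, path) -> None:
    """Per-worker out-of-fold probabilities and labels."""
    with open(path, "w", newline="") as fh:
        fh.write("id,oof_probability,label\n")
        for wid, p, y in zip(report.worker_ids, report.probabilities,
                             report.labels):
            fh.write(f"{wid},{float(p)!r},{int(y)}\n")


def write_stability_csv(stability: StabilityReport, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("factor,selection_frequency,mean_truncated_coefficient\n")
        for row in stability.as_rows():
            fh.write(f"{row['factor']},{row['selection_frequency']!r},"
                     f"{row['mean_truncated_coefficient']!r}\n")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``cohort_path`` (ingest) or ``simulate_n`` > 0
    (synthesize) supplies the cohort. All stage seeds are explicit so the
    manifest fully determines the outputs.
    """

    out_dir: Union[str, Path]
    cohort_path: Optional[str] = None
    simulate_n: int = 0
    simulate_seed: int = 0
    fit_seed: int = 0
    bootstrap_seed: int = 0
    penalty_lambda: Union[float, str] = "auto"
    bootstrap_B: int = 200
    cutoffs_path: Optional[str] = None
    vo2max_path: Optional[str] = None
    ndigits: int = 3
    refit_per_fold: bool = True

    def fingerprint(self) -> str:
        d = dataclasses.asdict(self)
        d["out_dir"] = None  # the hash covers content, not destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_config_objects(config: RunConfig) -> CutoffConfig:
    ref = (load_vo2max_reference(config.vo2max_path)
           if config.vo2max_path else None)
    return load_cutoffs(config.cutoffs_path, vo2max_reference=ref)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """simulate/ingest → code → fit → score → validate → bootstrap.

    Returns a name→path map of artifacts. Partial outputs are removed if
    any stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        written.append(path)
        return path

    artifacts: dict[str, Path] = {}
    try:
        cutoffs = _load_config_objects(config)
        if config.cohort_path:
            records = read_cohort_csv(config.cohort_path)
            log.info("ingested cohort: %d workers from %s",
                     len(records), config.cohort_path)
        else:
            if config.simulate_n <= 0:
                raise SchemaError(
                    "RunConfig needs cohort_path or simulate_n > 0"
                )
            records = generate_cohort(CohortParams(), config.simulate_n,
                                      config.simulate_seed)
            log.info("simulated cohort: %d workers (seed %d)",
                     len(records), config.simulate_seed)
            artifacts["cohort"] = _write("cohort.csv", write_cohort_csv,
                                         records)

        profiles = code_cohort(records, cutoffs)
        log.info("coded %d risk profiles", len(profiles))
        artifacts["profiles"] = _write("profiles.csv", write_profiles_csv,
                                       profiles)

        spec = FitSpec(penalty_lambda=config.penalty_lambda,
                       seed=config.fit_seed)
        weights, model, _ = fit_weights(profiles, records, spec)
        log.info("fitted weights at lambda=%.6g (degenerate=%s)",
                 model.penalty_lambda, weights.degenerate)
        artifacts["weights"] = _write("weights.json", write_weights_json,
                                      weights)

        scores = [compute_score(p, weights) for p in profiles]
        artifacts["scores"] = _write("scores.csv", write_scores_csv, scores)

        report = loocv(profiles, records, spec,
                       refit_per_fold=config.refit_per_fold)
        log.info("LOOCV: n=%d positives=%d auroc=%s",
                 report.n, report.positives, report.auroc)
        artifacts["report"] = _write(
            "report.json",
            lambda rep, path: write_report_json(rep, path, config.ndigits),
            report,
        )
        artifacts["oof"] = _write("oof_probabilities.csv", write_oof_csv,
                                  report)

        stability = bootstrap_stability(
            profiles, records, spec, B=config.bootstrap_B,
            master_seed=config.bootstrap_seed,
        )
        log.info("bootstrap: B=%d redraws=%d", stability.B, stability.redraws)
        artifacts["stability"] = _write("stability.csv", write_stability_csv,
                                        stability)

        manifest = {
            "package": {"name": "cssi", "version": __version__},
            "libraries": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "config": {**dataclasses.asdict(config),
                       "out_dir": str(config.out_dir)},
            "config_fingerprint": config.fingerprint(),
            "seeds": {
                "simulate": config.simulate_seed,
                "fit": config.fit_seed,
                "bootstrap": config.bootstrap_seed,
            },
            "artifacts": sorted(p.name for p in written) + ["manifest.json"],
        }
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
        artifacts["manifest"] = path
        return artifacts
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
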