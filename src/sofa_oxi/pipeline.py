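"""Cohort CSV schema, validated I/O, and the simulate -> score -> evaluate
pipeline with deterministic, manifest-logged artifacts.

Missing PaO2 is encoded as an *empty cell* — never 0, never an NA token —
so that absence of a blood gas cannot be silently confused with a value.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, GeneratedCohort, default_config, generate_cohort
from .evaluation import calibration_bootstrap, compare_methods, per_score_mortality
from .scoring import (
    ConvImputation,
    Method,
    PatientRecord,
    Vasopressor,
    score_cohort,
)
from .oxygenation import OxygenDelivery, OxygenDevice

__all__ = [
    "COHORT_COLUMNS",
    "CohortValidationError",
    "DegenerateOutcomeError",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

log = logging.getLogger("sofa_oxi")

COHORT_COLUMNS = [
    "patient_id",
    "spo2_pct",
    "pao2_mmhg",
    "device",
    "flow_lpm",
    "set_fio2",
    "platelets_k_ul",
    "bilirubin_mg_dl",
    "map_mmhg",
    "vasopressor_cat",
    "gcs",
    "creatinine_mg_dl",
    "died_in_hospital",
]


class CohortValidationError(ValueError):
    """Raised when cohort rows violate the schema; carries row-level detail."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "; ".join(errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        super().__init__(f"{len(errors)} invalid row(s): {preview}{more}")


class DegenerateOutcomeError(ValueError):
    """Raised when evaluation is impossible (single outcome class)."""


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a pipeline run (hashed into the manifest)."""

    cohort_path: Union[str, Path]
    out_dir: Union[str, Path]
    methods: tuple[Method, ...] = tuple(Method)
    conv_imputation: ConvImputation = ConvImputation.IMPUTE_PAO2_100
    auc_ci_mode: str = "delong"
    n_boot: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be non-empty")
        if Method.CONV not in self.methods:
            # the conventional method is the comparison reference
            object.__setattr__(self, "methods", (Method.CONV,) + tuple(self.methods))
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def to_dict(self) -> dict:
        return {
            "cohort_path": str(self.cohort_path),
            "out_dir": str(self.out_dir),
            "methods": [m.value for m in self.methods],
            "conv_imputation": self.conv_imputation.value,
            "auc_ci_mode": self.auc_ci_mode,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    x = float(x)
    if x == int(x):
        return str(int(x))
    return repr(x)


def write_cohort(
    records: Sequence[PatientRecord],
    path: Union[str, Path],
    truth: Optional[pd.DataFrame] = None,
) -> None:
    """Write the cohort CSV (and optionally a truth sidecar next to it)."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "patient_id": i,
                "spo2_pct": _fmt(r.spo2),
                "pao2_mmhg": _fmt(r.pao2),
                "device": r.delivery.device.value,
                "flow_lpm": _fmt(r.delivery.flow_lpm),
                "set_fio2": _fmt(r.delivery.set_fio2),
                "platelets_k_ul": _fmt(r.platelets),
                "bilirubin_mg_dl": _fmt(r.bilirubin),
                "map_mmhg": _fmt(r.map_mmhg),
                "vasopressor_cat": r.vasopressor.value,
                "gcs": r.gcs,
                "creatinine_mg_dl": _fmt(r.creatinine),
                "died_in_hospital": int(r.died_in_hospital),
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
    if truth is not None:
        sidecar = Path(path).with_suffix(".truth.csv")
        truth.to_csv(sidecar, index=False, float_format="%.10g")


def _parse_row(row: pd.Series) -> PatientRecord:
    def opt(name: str) -> Optional[float]:
        v = row[name]
        if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
            return None
        return float(v)

    delivery = OxygenDelivery(
        device=OxygenDevice(str(row["device"])),
        flow_lpm=opt("flow_lpm"),
        set_fio2=opt("set_fio2"),
    )
    died = int(row["died_in_hospital"])
    if died not in (0, 1):
        raise ValueError(f"died_in_hospital must be 0 or 1, got {died}")
    return PatientRecord(
        spo2=float(row["spo2_pct"]),
        pao2=opt("pao2_mmhg"),
        delivery=delivery,
        platelets=float(row["platelets_k_ul"]),
        bilirubin=float(row["bilirubin_mg_dl"]),
        map_mmhg=float(row["map_mmhg"]),
        vasopressor=Vasopressor(str(row["vasopressor_cat"])),
        gcs=int(row["gcs"]),
        creatinine=float(row["creatinine_mg_dl"]),
        died_in_hospital=bool(died),
    )


def read_cohort(
    path: Union[str, Path], skip_invalid: bool = False
) -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Every row is validated against the patient-record invariants; errors are
    collected with row numbers and raised together as
    :class:`CohortValidationError` (or logged and skipped with
    ``skip_invalid``). An empty ``pao2_mmhg`` cell parses as missing.
    """
    df = pd.read_csv(path, dtype={"pao2_mmhg": "object", "flow_lpm": "object",
                                  "set_fio2": "object"})
    if list(df.columns) != COHORT_COLUMNS:
        raise CohortValidationError(
            [f"header mismatch: expected {COHORT_COLUMNS}, got {list(df.columns)}"]
        )
    if df["patient_id"].duplicated().any():
        dupes = df["patient_id"][df["patient_id"].duplicated()].tolist()[:5]
        raise CohortValidationError([f"duplicate patient_id values: {dupes}"])

    records: list[PatientRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(_parse_row(row))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based lines
    if errors and not skip_invalid:
        raise CohortValidationError(errors)
    if errors:
        log.warning("skipped %d invalid rows", len(errors))
    log.info("read %d records from %s", len(records), path)
    return records


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Score a cohort under every requested method and evaluate the results.

    Emits, under ``config.out_dir``:

    * ``scores.csv`` — per-patient respiratory and total score per method
    * ``comparison.csv`` / ``comparison.json`` — AUROC + 95% CI per method
      and score type, with DeLong p vs the conventional method
    * ``per_score_mortality.csv`` — observed mortality with exact binomial
      CIs per respiratory-score level, per method
    * ``calibration.csv`` — bootstrap percentile calibration bands
    * ``manifest.json`` — seed, config hash, package version, row counts

    Outputs are fully determined by (cohort file, config); reruns are
    byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_cohort(config.cohort_path)
    labels = np.array([r.died_in_hospital for r in records], dtype=bool)
    if labels.all() or not labels.any():
        raise DegenerateOutcomeError(
            "cohort has a single outcome class; AUROC evaluation undefined"
        )

    methods = list(config.methods)
    scores = score_cohort(records, methods, config.conv_imputation)
    log.info("scored %d records under %d methods", len(records), len(methods))
    _write_csv(scores, out / "scores.csv")

    comparison = compare_methods(
        records, methods, config.conv_imputation,
        ci_mode=config.auc_ci_mode, scores=scores,
    )
    _write_csv(comparison, out / "comparison.csv")
    (out / "comparison.json").write_text(
        json.dumps(comparison.to_dict(orient="records"), indent=2, allow_nan=True)
        + "\n"
    )

    mort_rows = []
    calib_rows = []
    for m in methods:
        resp = scores[f"resp_{m.value}"].to_numpy(dtype=float)
        tab = per_score_mortality(resp, labels)
        tab.insert(0, "method", m.value)
        mort_rows.append(tab)
        cal = calibration_bootstrap(resp, labels, n_boot=config.n_boot, seed=config.seed)
        calib_rows.append(
            pd.DataFrame(
                {
                    "method": m.value,
                    "score": cal.levels,
                    "n": cal.n_per_level,
                    "observed": cal.observed,
                    "ci_low": cal.ci_low,
                    "ci_high": cal.ci_high,
                }
            )
        )
    _write_csv(pd.concat(mort_rows, ignore_index=True), out / "per_score_mortality.csv")
    _write_csv(pd.concat(calib_rows, ignore_index=True), out / "calibration.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "n_records": len(records),
        "n_events": int(labels.sum()),
        "artifacts": [
            "scores.csv",
            "comparison.csv",
            "comparison.json",
            "per_score_mortality.csv",
            "calibration.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote %d artifacts to %s", len(manifest["artifacts"]) + 1, out)
    return {name: out / name for name in manifest["artifacts"] + ["manifest.json"]}


def reproduce(
    seed: int,
    out_dir: Union[str, Path],
    n: Optional[int] = None,
    n_boot: int = 100,
) -> dict[str, Path]:
    """One-shot driver: simulate the default cohort, score it, evaluate it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config(n=n, seed=seed)
    cohort = generate_cohort(cfg)
    cohort_path = out / "cohort.csv"
    write_cohort(cohort.records, cohort_path, truth=cohort.truth)
    run = RunConfig(cohort_path=cohort_path, out_dir=out, seed=seed, n_boot=n_boot)
    artifacts = run_pipeline(run)
    artifacts["cohort.csv"] = cohort_path
    return artifacts
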