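"""End-to-end orchestration: ingest -> classify -> score -> evaluate -> report.

:func:`ingest` reads a cohort CSV in the documented schema, excluding rows
with no risk-assessment data at all (field-level missingness is only
logged). :func:`run` executes the whole pipeline and writes the report
bundle — incidence CSV, diagnostics CSV, JSON report, and a run log. The
JSON report is byte-stable across reruns except for its single timestamp
field.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .diagnostics import EvaluationReport, evaluate
from .errors import SchemaError
from .outcomes import composite_frame
from .risk_rules import classify_frame
from .schema import ASSESSMENT_COLUMNS, REQUIRED_COLUMNS
from .synthetic_cohort import CohortSpec, default_spec, generate
from .thresholds import DEFAULT_THRESHOLDS

logger = logging.getLogger("hemrisk")

_BOOL_COLUMNS = tuple(
    c for c in REQUIRED_COLUMNS
    if c not in (
        "prior_vaginal_births", "prior_pph_count", "bmi",
        "estimated_fetal_weight", "hematocrit", "platelets",
        "ebl_ml", "prbc_units",
    )
)
_INT_COLUMNS = ("prior_vaginal_births", "prior_pph_count", "prbc_units")
_FLOAT_COLUMNS = ("bmi", "estimated_fetal_weight", "hematocrit", "platelets", "ebl_ml")


@dataclass
class IngestResult:
    """Typed cohort plus an ingest audit trail."""

    frame: pd.DataFrame
    n_rows_read: int
    n_excluded: int
    excluded_rows: list[int]
    field_missing_counts: dict[str, int]
    extra_columns: list[str]


def ingest(path: str | Path) -> IngestResult:
    """Read and type-check a cohort CSV.

    Rows where every risk-assessment field is empty are excluded (they
    cannot be scored) and reported in the result; partially missing rows are
    kept, with per-field missingness counted. Malformed (non-numeric) cells
    raise :class:`~hemrisk.errors.SchemaError` naming row and column.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")
    extra = [c for c in raw.columns if c not in REQUIRED_COLUMNS]

    n_read = len(raw)
    assessment = raw[list(ASSESSMENT_COLUMNS)]
    all_missing = assessment.isna().all(axis=1)
    excluded_rows = [int(i) for i in raw.index[all_missing]]
    kept = raw.loc[~all_missing].copy()

    bad_cells: list[str] = []
    typed = pd.DataFrame(index=kept.index)
    for col in REQUIRED_COLUMNS:
        numeric = pd.to_numeric(kept[col], errors="coerce")
        malformed = numeric.isna() & kept[col].notna()
        for i in kept.index[malformed]:
            bad_cells.append(f"row {int(i) + 2}, column {col!r}: {kept.at[i, col]!r}")
        typed[col] = numeric
    if bad_cells:
        raise SchemaError("malformed cells: " + "; ".join(bad_cells[:20]))

    field_missing = {
        c: int(typed[c].isna().sum())
        for c in REQUIRED_COLUMNS
        if typed[c].isna().any()
    }
    for col in _BOOL_COLUMNS:
        typed[col] = typed[col].fillna(0).astype(bool)
    for col in _INT_COLUMNS:
        typed[col] = typed[col].fillna(0).astype(np.int64)
    if "recorded_level" in extra:
        typed["recorded_level"] = kept["recorded_level"]

    if excluded_rows:
        logger.info("excluded %d rows with no assessment data", len(excluded_rows))
    return IngestResult(
        frame=typed.reset_index(drop=True),
        n_rows_read=n_read,
        n_excluded=len(excluded_rows),
        excluded_rows=excluded_rows,
        field_missing_counts=field_missing,
        extra_columns=extra,
    )


class RunConfig(BaseModel):
    """Configuration for one pipeline run."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    input: Optional[Path] = None   # None -> simulate the default cohort
    out_dir: Path
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0
    spec: Optional[CohortSpec] = None
    use_recorded_level: bool = False
    log_level: str = "INFO"


def _report_dict(
    report: EvaluationReport, ingest_log: dict, seed: int
) -> dict:
    contrasts = {}
    for name, s in report.contrasts.items():
        contrasts[name] = {
            "table": dataclasses.asdict(s.table),
            "full_precision": {
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
                "ppv": s.ppv,
                "npv": s.npv,
                "dor": s.dor,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            },
            "display": {
                "sensitivity": round(s.sensitivity, 2),
                "specificity": round(s.specificity, 2),
                "ppv": round(s.ppv, 2),
                "npv": round(s.npv, 2),
                "dor": round(s.dor, 2),
                "ci": [round(s.ci_low, 2), round(s.ci_high, 2)],
            },
            "correction_applied": s.correction_applied,
        }
    return {
        "version": __version__,
        "seed": seed,
        "alpha": report.alpha,
        "ingest": ingest_log,
        "incidence": report.incidence.to_dict(orient="records"),
        "contrasts": contrasts,
        "timestamp": None,  # filled just before writing; sole volatile field
    }


def run(config: RunConfig) -> dict:
    """Execute the pipeline and write the report bundle.

    Returns the report dictionary (as written to ``report.json``).
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input is not None:
        ing = ingest(config.input)
        cohort = ing.frame
        ingest_log = {
            "source": str(config.input),
            "rows_read": ing.n_rows_read,
            "rows_excluded": ing.n_excluded,
            "excluded_rows": ing.excluded_rows,
            "field_missing_counts": ing.field_missing_counts,
            "extra_columns": ing.extra_columns,
        }
    else:
        spec = config.spec or default_spec(seed=config.seed)
        if spec.seed != config.seed:
            spec = spec.model_copy(update={"seed": config.seed})
        cohort = generate(spec)
        ingest_log = {
            "source": "synthetic:default_spec",
            "rows_read": len(cohort),
            "rows_excluded": 0,
            "excluded_rows": [],
            "field_missing_counts": {},
            "extra_columns": ["recorded_level"],
        }

    if config.use_recorded_level:
        if "recorded_level" not in cohort.columns:
            raise SchemaError("use_recorded_level set but no recorded_level column")
        levels = cohort["recorded_level"].to_numpy()
    else:
        levels = classify_frame(cohort)["level"].to_numpy()
    flags = composite_frame(cohort)
    report = evaluate(levels, flags, alpha=config.alpha)

    report.incidence.to_csv(out_dir / "incidence.csv", index=False)
    report.diagnostics_frame().to_csv(out_dir / "diagnostics.csv", index=False)
    payload = _report_dict(report, ingest_log, config.seed)
    payload["timestamp"] = datetime.now(timezone.utc).isoformat()
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
    log = {
        "records_in": ingest_log["rows_read"],
        "records_excluded": ingest_log["rows_excluded"],
        "records_analyzed": int(len(cohort)),
        "seed": config.seed,
        "alpha": config.alpha,
        "version": __version__,
        "thresholds": dataclasses.asdict(DEFAULT_THRESHOLDS),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return payload
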