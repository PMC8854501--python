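"""Cohort file I/O: demographics and long-format series CSVs, config files.

File schemas
------------
demographics CSV: header ``patient_id,age_years,bmi``; one row per patient.

series CSV (long format): header ``patient_id,t_index,tofr,observed``;
``t_index`` is the 0-based sample index on the 15-s grid; ``observed`` is
0/1; missing values are written as an empty ``tofr`` field with
``observed=0``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .synthetic_cohort import GeneratorConfig, PatientRecord, TOFRSeries

__all__ = [
    "write_cohort",
    "read_cohort",
    "load_generator_config",
    "save_report_json",
]

DEMOGRAPHICS_COLUMNS = ["patient_id", "age_years", "bmi"]
SERIES_COLUMNS = ["patient_id", "t_index", "tofr", "observed"]


def write_cohort(
    cohort: Sequence[PatientRecord], demographics_path: str | Path, series_path: str | Path
) -> None:
    """Write a cohort to the two-CSV on-disk format."""
    demo = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in cohort],
            "age_years": [r.age for r in cohort],
            "bmi": [r.bmi for r in cohort],
        }
    )
    demo.to_csv(demographics_path, index=False)

    frames: List[pd.DataFrame] = []
    for r in cohort:
        s = r.series
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": r.patient_id,
                    "t_index": np.arange(len(s)),
                    "tofr": s.values,
                    "observed": s.observed.astype(int),
                }
            )
        )
    series = pd.concat(frames, ignore_index=True)
    # missing samples serialise as an empty tofr field
    series.to_csv(series_path, index=False, na_rep="")


def read_cohort(demographics_path: str | Path, series_path: str | Path) -> List[PatientRecord]:
    """Load a cohort from the two-CSV format, validating the schema.

    Series rows are joined to demographics on ``patient_id``; rows must be
    unique per (patient_id, t_index) and every patient needs at least one
    series point.  An empty ``tofr`` field with ``observed=0`` becomes a
    masked sample.
    """
    demo = pd.read_csv(demographics_path)
    if list(demo.columns) != DEMOGRAPHICS_COLUMNS:
        raise SchemaError(
            f"demographics header must be {DEMOGRAPHICS_COLUMNS}, got {list(demo.columns)}"
        )
    if demo["patient_id"].duplicated().any():
        dupes = demo.loc[demo["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient_id in demographics: {dupes}")
    for col in ("age_years", "bmi"):
        if not pd.api.types.is_numeric_dtype(demo[col]) or demo[col].isna().any():
            raise SchemaError(f"non-numeric or missing {col} in demographics")

    series = pd.read_csv(series_path)
    if list(series.columns) != SERIES_COLUMNS:
        raise SchemaError(f"series header must be {SERIES_COLUMNS}, got {list(series.columns)}")
    known = set(demo["patient_id"])
    orphans = sorted(set(series["patient_id"]) - known)
    if orphans:
        raise SchemaError(f"series rows reference unknown patient_id(s): {orphans}")
    if series.duplicated(subset=["patient_id", "t_index"]).any():
        bad = series.loc[
            series.duplicated(subset=["patient_id", "t_index"]), ["patient_id", "t_index"]
        ]
        raise SchemaError(f"duplicate (patient_id, t_index) rows: {bad.values.tolist()[:5]}")

    cohort: List[PatientRecord] = []
    grouped = dict(tuple(series.groupby("patient_id", sort=False)))
    for row in demo.itertuples(index=False):
        g = grouped.get(row.patient_id)
        if g is None or len(g) == 0:
            raise SchemaError(f"patient {row.patient_id!r} has no series points")
        g = g.sort_values("t_index")
        t = g["t_index"].to_numpy()
        if t[0] != 0 or not np.array_equal(t, np.arange(len(t))):
            raise SchemaError(f"patient {row.patient_id!r}: t_index must be contiguous from 0")
        observed = g["observed"].to_numpy().astype(bool)
        values = g["tofr"].to_numpy(dtype=float)
        if np.any(observed & ~np.isfinite(values)):
            raise SchemaError(f"patient {row.patient_id!r}: observed rows must carry a tofr value")
        values = np.where(observed, values, np.nan)
        cohort.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                age=float(row.age_years),
                bmi=float(row.bmi),
                series=TOFRSeries(values=values, observed=observed),
            )
        )
    return cohort


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a GeneratorConfig from a YAML or JSON file mirroring its fields."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"config file {path} must hold a mapping")
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SchemaError(f"unknown generator config fields: {unknown}")
    for key in ("length_range", "age_range", "bmi_range", "end_value_range"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    config = GeneratorConfig(**data)
    config.validate()
    return config


def write_predictions_csv(rows: Sequence[tuple], path: str | Path) -> None:
    """Write walk-forward predictions, one row per (patient, test index).

    ``rows`` holds (patient_id, t_index, observed, predicted) tuples; the
    resulting CSV feeds the ``plot`` command.
    """
    df = pd.DataFrame(rows, columns=["patient_id", "t_index", "observed", "predicted"])
    df.to_csv(path, index=False)


def save_report_json(report, path: str | Path) -> None:
    """Write an ExperimentReport to JSON at full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, allow_nan=True))
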