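"""Readers and writers for the interchange tables and reports.

Cohort CSV (long format): subject_id, group (coa|control), weight_kg,
method (manual|intelligent), site (AOA|D1|D2|D3|DA), diameter_mm.
Predictions CSV: subject_id, method, criterion, predicted_label,
triggered_conditions.  JSON reports carry a schema_version field.
Unknown extra columns are preserved; missing required ones raise
SchemaError naming the column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .diagnosis import SiteMeasurements
from .errors import SchemaError
from .phantoms import COHORT_COLUMNS, SITES

GROUPS = ("coa", "control")
METHODS = ("manual", "intelligent")
PREDICTION_COLUMNS = ["subject_id", "method", "criterion", "predicted_label", "triggered_conditions"]
REPORT_SCHEMA_VERSION = 1


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:  # grayscale -> replicate channels
        img = np.stack([img] * 3, axis=-1)
    return np.asarray(img[..., :3], dtype=np.uint8)


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def _check_vocab(df: pd.DataFrame, column: str, allowed: tuple[str, ...]) -> None:
    if len(df) == 0:
        return
    bad = set(df[column].unique()) - set(allowed)
    if bad:
        raise SchemaError(f"column {column!r} contains unknown values {sorted(bad)}")


def read_cohort_csv(path: str | Path, require_weight: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = [c for c in COHORT_COLUMNS if c != "weight_kg"]
    if require_weight:
        required = list(COHORT_COLUMNS)
    _check_columns(df, required, "cohort table")
    _check_vocab(df, "group", GROUPS)
    _check_vocab(df, "method", METHODS)
    _check_vocab(df, "site", SITES)
    if len(df) and (df["diameter_mm"] <= 0).any():
        raise SchemaError("column 'diameter_mm' contains non-positive values")
    return df


def write_cohort_csv(path: str | Path, df: pd.DataFrame) -> None:
    _check_columns(df, [c for c in COHORT_COLUMNS if c != "weight_kg"], "cohort table")
    df.to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PREDICTION_COLUMNS[:4], "predictions table")
    return df


def write_predictions_csv(path: str | Path, df: pd.DataFrame) -> None:
    _check_columns(df, PREDICTION_COLUMNS[:4], "predictions table")
    df.to_csv(path, index=False)


def write_report_json(path: str | Path, report: dict) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def subject_measurements(cohort: pd.DataFrame, method: str, require_weight: bool = False):
    """Yield (subject_id, SiteMeasurements) for one method, wide per subject."""
    sub = cohort[cohort["method"] == method]
    for sid, grp in sub.groupby("subject_id", sort=True):
        values = dict(zip(grp["site"], grp["diameter_mm"]))
        weight = None
        if "weight_kg" in grp.columns and grp["weight_kg"].notna().any():
            weight = float(grp["weight_kg"].iloc[0])
        if require_weight and weight is None:
            raise SchemaError(f"subject {sid!r} lacks required column weight_kg")
        yield sid, SiteMeasurements(
            aoa=values.get("AOA"),
            d1=values.get("D1"),
            d2=values.get("D2"),
            d3=values.get("D3"),
            da=values.get("DA"),
            weight_kg=weight,
        )
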