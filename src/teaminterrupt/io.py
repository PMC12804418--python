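"""Decision-event CSV schema, validation, and ground-truth sidecar files."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .decision_models import DECISION_TYPES

#: required columns of the decision-event table, in canonical order
EVENT_COLUMNS = [
    "subject_id",
    "block",
    "decision_type",
    "tp_interrupter",
    "tp_interruptee",
    "outcome",
    "time_available",
    "deadline_condition",
    "error_impact_condition",
]

_FITTED_COLUMNS = ["tp_interrupter", "tp_interruptee", "outcome"]


class SchemaError(ValueError):
    """A decision-event table violates the CSV schema."""


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a decision-event table against the schema.

    Checks required columns, missing values in fitted columns, binary
    outcomes, valid decision types, and finite non-negative time pressures.
    Extra columns (e.g. progress covariates from the simulator) are allowed.
    Returns the frame unchanged on success.
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if df[_FITTED_COLUMNS].isna().any().any():
        raise SchemaError("missing values in fitted columns")
    if not df["outcome"].isin([0, 1]).all():
        raise SchemaError("outcome must be binary 0/1")
    bad_types = set(df["decision_type"].unique()) - set(DECISION_TYPES)
    if bad_types:
        raise SchemaError(f"unknown decision_type values: {sorted(bad_types)}")
    tp = df[["tp_interrupter", "tp_interruptee"]].to_numpy(float)
    if not np.isfinite(tp).all() or (tp < 0).any():
        raise SchemaError("time pressures must be finite and >= 0")
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate a decision-event CSV."""
    df = pd.read_csv(path)
    return validate_events(df)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated decision-event CSV (canonical columns first)."""
    validate_events(df)
    ordered = EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[ordered].to_csv(path, index=False)


def data_fingerprint(df: pd.DataFrame) -> str:
    """Stable hash of the fitted content of an event table.

    Used to refuse model comparisons across different datasets.
    """
    sub = df[EVENT_COLUMNS].reset_index(drop=True)
    payload = sub.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    """Write a JSON document, coercing numpy scalars/arrays to plain types."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
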