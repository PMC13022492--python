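"""Readers and writers: prediction tables, feature tables, JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_EPS, PredictionSet
from .exceptions import ValidationError

SCHEMA_VERSION = 1


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_prediction_table(path, eps: float = DEFAULT_EPS) -> PredictionSet:
    """Read a CSV/TSV with columns ``y``, ``p_ref``, ``p_new`` into a
    validated :class:`PredictionSet` (clipping applied with ``eps``)."""
    df = _read_table(path)
    missing = [c for c in ("y", "p_ref", "p_new") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    bad = df.index[~df["y"].isin([0, 1])]
    if len(bad):
        raise ValidationError(
            f"{path}: non-binary outcome at row(s) {list(bad[:5])} "
            f"(values {df['y'].iloc[bad[:5]].tolist()})"
        )
    return PredictionSet(
        y=df["y"].to_numpy(), p_ref=df["p_ref"].to_numpy(),
        p_new=df["p_new"].to_numpy(), eps=eps,
    )


def read_feature_table(path, outcome: str = "y") -> tuple[pd.DataFrame, pd.Series]:
    """Read a CSV/TSV feature matrix; split off the binary outcome column."""
    df = _read_table(path)
    if outcome not in df.columns:
        raise ValidationError(f"{path}: outcome column {outcome!r} not found")
    y = df[outcome]
    if not y.isin([0, 1]).all():
        raise ValidationError(f"{path}: outcome column {outcome!r} is not 0/1")
    return df.drop(columns=[outcome]), y.astype(int)


def to_jsonable(obj):
    """Recursively convert results (dataclasses, numpy, estimators) to JSON types."""
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if hasattr(obj, "to_dict"):
        return to_jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj):
        return to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [to_jsonable(v) for v in obj]
    return str(obj)


def write_report(results, path, config: dict | None = None):
    """Write a JSON report with schema version and config echo at full precision."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": to_jsonable(config or {}),
        "results": to_jsonable(results),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
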