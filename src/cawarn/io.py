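"""CSV/JSON interfaces for records, labels, grids, features and reports.

All numeric payloads round-trip at full precision (shortest-repr floats).
Malformed rows are rejected with their 1-based file line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cawarn.errors import DataError
from cawarn.features import FeatureTable
from cawarn.preprocess import RegularGrid

OBSERVATION_COLUMNS = ["stay_id", "time_hours", "channel", "value"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> pd.DataFrame:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise DataError(f"{path}: non-numeric {col!r} at line {line}")
    if coerced.isna().any():
        line = int(coerced.isna().idxmax()) + 2
        raise DataError(f"{path}: empty {col!r} at line {line}")
    df = df.copy()
    df[col] = coerced
    return df


def read_observations(path) -> pd.DataFrame:
    """Long-format observation records: stay_id, time_hours, channel, value."""
    df = pd.read_csv(path, dtype={"stay_id": str, "channel": str})
    _require_columns(df, OBSERVATION_COLUMNS, path)
    df = _coerce_numeric(df, "time_hours", path)
    df = _coerce_numeric(df, "value", path)
    if (df["time_hours"] < 0).any():
        line = int((df["time_hours"] < 0).idxmax()) + 2
        raise DataError(f"{path}: negative time_hours at line {line}")
    return df[OBSERVATION_COLUMNS]


def write_observations(records: pd.DataFrame, path) -> None:
    records[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_labels(path) -> dict:
    df = pd.read_csv(path, dtype={"stay_id": str})
    _require_columns(df, ["stay_id", "label"], path)
    df = _coerce_numeric(df, "label", path)
    if not set(df["label"].unique()) <= {0, 1}:
        raise DataError(f"{path}: labels must be binary")
    return dict(zip(df["stay_id"], df["label"].astype(int)))


def write_labels(labels: dict, path) -> None:
    pd.DataFrame({"stay_id": list(labels), "label": [int(v) for v in labels.values()]}).to_csv(
        path, index=False
    )


def write_grids(grids, path) -> None:
    """Wide format: one row per stay-hour, one column per channel."""
    frames = []
    for g in grids:
        frame = pd.DataFrame(g.values, columns=g.channels)
        frame.insert(0, "hour", np.arange(g.T))
        frame.insert(0, "stay_id", g.stay_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_grids(path) -> dict:
    df = pd.read_csv(path, dtype={"stay_id": str})
    _require_columns(df, ["stay_id", "hour"], path)
    channels = [c for c in df.columns if c not in ("stay_id", "hour")]
    grids = {}
    for stay_id, sub in df.groupby("stay_id", sort=True):
        sub = sub.sort_values("hour")
        grids[str(stay_id)] = RegularGrid(
            stay_id=str(stay_id), values=sub[channels].to_numpy(), channels=channels
        )
    return grids


def write_feature_table(ft: FeatureTable, path) -> None:
    out = ft.X.copy()
    out["label"] = ft.y
    out.to_csv(path, index=True)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, index_col="stay_id")
    if "label" not in df.columns:
        raise DataError(f"{path}: missing required column 'label'")
    y = df.pop("label").astype(int)
    return FeatureTable(X=df, y=y.rename("label"))


def write_report(report, out_json, out_csv=None) -> None:
    """EvalReport as JSON (summary, CIs, config, lead curve) + per-fold CSV."""
    payload = {
        "summary": report.summary,
        "ci": {m: list(v) for m, v in report.ci.items()},
        "config": report.config,
    }
    if report.lead_curve is not None:
        payload["lead_time_auroc"] = {str(k): v for k, v in report.lead_curve.items()}
    Path(out_json).write_text(json.dumps(payload, indent=2))
    if out_csv is not None:
        report.fold_metrics.to_csv(out_csv)
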