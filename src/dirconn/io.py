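"""Delimited-text readers and writers.

Time series are TSV with one row per region: first column the region label,
remaining columns the time points (header optional).  Matrices are square TSV
tables with region labels as header row and first column, accompanied by a
JSON sidecar carrying provenance (method, lag, clipped, subject_id).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConnectivityMatrix, RegionTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "read_subjects",
    "write_subjects",
]


def read_timeseries(
    path, sep: str = "\t", header: bool = False, subject_id: str | None = None, tr_seconds: float = 1.0
) -> RegionTimeSeries:
    df = pd.read_csv(path, sep=sep, header=0 if header else None, float_precision="round_trip")
    labels = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    sid = subject_id if subject_id is not None else Path(path).stem
    return RegionTimeSeries(data=data, region_labels=labels, subject_id=sid, tr_seconds=tr_seconds)


def write_timeseries(ts: RegionTimeSeries, path, sep: str = "\t", header: bool = False) -> None:
    df = pd.DataFrame(ts.data, index=ts.region_labels)
    df.columns = [f"t{c}" for c in df.columns]
    df.to_csv(path, sep=sep, header=header, index=True, float_format="%.17g")


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_matrix(mat: ConnectivityMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(mat.weights, index=mat.region_labels, columns=mat.region_labels)
    df.to_csv(path, sep=sep, float_format="%.17g")
    meta = {
        "method": mat.method,
        "lag": int(mat.lag),
        "clipped": bool(mat.clipped),
        "subject_id": mat.subject_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_matrix(path, sep: str = "\t") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ConnectivityMatrix(
        weights=df.to_numpy(dtype=float),
        method=meta.get("method", "lagged"),
        lag=int(meta.get("lag", 0)),
        clipped=bool(meta.get("clipped", False)),
        region_labels=[str(c) for c in df.columns],
        subject_id=meta.get("subject_id", Path(path).stem),
    )


def read_subjects(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if "subject_id" not in df.columns:
        raise ValueError("subject table must have a 'subject_id' column")
    return df


def write_subjects(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
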