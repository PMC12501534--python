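"""Reading and writing sensor logs, event lists and analysis reports.

One canonical log dialect is used throughout: a CSV (or its JSON mirror,
identical keys mapped to per-column lists) with columns

    t,
    q_trunk_w, q_trunk_x, q_trunk_y, q_trunk_z,
    q_ua_w,    q_ua_x,    q_ua_y,    q_ua_z,
    q_fa_w,    q_fa_x,    q_fa_y,    q_fa_z,
    fsr_u1…fsr_u8, fsr_l1…fsr_l8

Missing-data policy: a sample row with ANY missing field is dropped whole
(with a logged count) — never interpolated at load time, mirroring the
complete-cycles-only analysis policy downstream.  Quaternions are
renormalized on load; duplicate or non-increasing timestamps are rejected.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import AgreementReport, BlandAltman
from .cycles import CycleSummary
from .datatypes import EventList, GraspEvent, Recording, ReferenceSeries

__all__ = [
    "RECORDING_COLUMNS",
    "read_recording",
    "write_recording",
    "read_reference",
    "write_reference",
    "read_events",
    "write_events",
    "write_report",
    "read_report",
    "load_config",
]

logger = logging.getLogger(__name__)

_QUAT_COLS = [
    f"q_{seg}_{c}" for seg in ("trunk", "ua", "fa") for c in ("w", "x", "y", "z")
]
_FSR_COLS = [f"fsr_u{i}" for i in range(1, 9)] + [f"fsr_l{i}" for i in range(1, 9)]
RECORDING_COLUMNS = ["t"] + _QUAT_COLS + _FSR_COLS


class FormatError(ValueError):
    """Malformed file header or structure."""


def _load_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: JSON recording must be an object of columns")
        df = pd.DataFrame({k: data[k] for k in data})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df[RECORDING_COLUMNS]


def read_recording(path: str | Path, dialect: str = "csv") -> Recording:
    """Load and validate a sensor log.

    Rows with any missing field are dropped (logged); fewer than 2 valid
    rows, non-monotonic timestamps or zero quaternions raise.
    """
    df = _load_frame(path, dialect)
    n_raw = len(df)
    df = df.dropna()
    dropped = n_raw - len(df)
    if dropped:
        logger.info("read_recording(%s): dropped %d incomplete row(s)", path, dropped)
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows after dropping incomplete ones")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing (duplicates rejected)")
    quats = {
        seg: df[[f"q_{seg}_{c}" for c in "wxyz"]].to_numpy(dtype=float)
        for seg in ("trunk", "ua", "fa")
    }
    dt = np.median(np.diff(t))
    return Recording(
        timestamps=t,
        trunk_quat=quats["trunk"],
        upperarm_quat=quats["ua"],
        forearm_quat=quats["fa"],
        fsr_upper=df[[f"fsr_u{i}" for i in range(1, 9)]].to_numpy(dtype=float),
        fsr_lower=df[[f"fsr_l{i}" for i in range(1, 9)]].to_numpy(dtype=float),
        rate_hz=float(1.0 / dt),
    )


def _recording_frame(rec: Recording) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"t": rec.timestamps}
    for seg, q in (("trunk", rec.trunk_quat), ("ua", rec.upperarm_quat), ("fa", rec.forearm_quat)):
        for j, c in enumerate("wxyz"):
            cols[f"q_{seg}_{c}"] = q[:, j]
    for j in range(8):
        cols[f"fsr_u{j + 1}"] = rec.fsr_upper[:, j]
    for j in range(8):
        cols[f"fsr_l{j + 1}"] = rec.fsr_lower[:, j]
    return pd.DataFrame(cols)


def write_recording(rec: Recording, path: str | Path, dialect: str = "csv") -> None:
    """Write a Recording in the canonical dialect (full float precision,
    so read∘write round-trips to 1e-9 and better)."""
    df = _recording_frame(rec)
    path = Path(path)
    if dialect == "csv":
        df.to_csv(path, index=False)
    elif dialect == "json":
        with open(path, "w") as fh:
            json.dump({c: df[c].tolist() for c in df.columns}, fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_reference(path: str | Path, label: str = "") -> ReferenceSeries:
    """Load a reference series CSV with columns ``t, value``."""
    df = pd.read_csv(path)
    for col in ("t", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: reference CSV needs columns 't, value'")
    df = df.dropna()
    t = df["t"].to_numpy(dtype=float)
    rate = float(1.0 / np.median(np.diff(t))) if len(t) > 1 else 100.0
    return ReferenceSeries(timestamps=t, values=df["value"].to_numpy(dtype=float),
                           rate_hz=rate, label=label)


def write_reference(series: ReferenceSeries, path: str | Path) -> None:
    pd.DataFrame({"t": series.timestamps, "value": series.values}).to_csv(path, index=False)


def write_events(events: EventList, path: str | Path, meta: dict | None = None) -> None:
    payload = {
        "source": events.source,
        "events": [
            {"onset": e.onset, "offset": e.offset,
             "peak_value": None if np.isnan(e.peak_value) else e.peak_value}
            for e in events
        ],
    }
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_events(path: str | Path) -> EventList:
    with open(path) as fh:
        data = json.load(fh)
    events = [
        GraspEvent(
            onset=float(e["onset"]),
            offset=float(e["offset"]),
            peak_value=float("nan") if e.get("peak_value") is None else float(e["peak_value"]),
        )
        for e in data["events"]
    ]
    return EventList(events=events, source=data.get("source", "fsr"))


def _json_safe(x):
    """NaN/inf → None (an explicit null marker, never silently omitted)."""
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_json_safe(v) for v in x]
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    if isinstance(x, (np.floating, float)):
        return None if not np.isfinite(x) else float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    return x


def _ba_dict(ba: BlandAltman | None) -> dict | None:
    if ba is None:
        return None
    return {
        "bias": ba.bias, "sd": ba.sd,
        "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
        "pct_within": ba.pct_within,
        "means": list(ba.means), "diffs": list(ba.diffs),
    }


def report_to_dict(report: AgreementReport | CycleSummary) -> dict:
    """Plain-dict form of a report (NaN rendered as null on serialization)."""
    if isinstance(report, AgreementReport):
        per_cycle = [
            {
                "cycle": i,
                "cmc": report.cmc_values[i],
                "cmc_undefined": bool(report.cmc_undefined[i]),
                "rmse_deg": report.rmse_deg[i],
                "rrmse_pct": report.rrmse_pct[i],
            }
            for i in range(len(report.cmc_values))
        ]
        return {
            "type": "agreement",
            "per_cycle": per_cycle,
            "summary": {
                "mean_cmc": report.mean_cmc,
                "mean_rmse_deg": report.mean_rmse,
                "mean_rrmse_pct": report.mean_rrmse,
                "n_cmc_undefined": report.n_cmc_undefined,
                "sync_lag_s": report.sync_lag_s,
            },
            "bland_altman": {"max": _ba_dict(report.ba_max), "min": _ba_dict(report.ba_min)},
        }
    if isinstance(report, CycleSummary):
        return {
            "type": "cycle_summary",
            "per_cycle": report.per_cycle.to_dict(orient="records"),
            "aggregate": report.aggregate,
        }
    raise TypeError(f"cannot serialize {type(report).__name__}")


def write_report(report: AgreementReport | CycleSummary | dict,
                 path: str | Path, meta: dict | None = None) -> None:
    """Write a report as JSON (machine) plus a per-cycle CSV table.

    Undefined statistics (NaN) are serialized as explicit JSON nulls.  The
    CSV sits next to the JSON with a ``.csv`` suffix.
    """
    data = report if isinstance(report, dict) else report_to_dict(report)
    if meta:
        data = {**data, "meta": meta}
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_json_safe(data), fh, indent=2)
    if "per_cycle" in data and data["per_cycle"]:
        pd.DataFrame(data["per_cycle"]).to_csv(path.with_suffix(".csv"), index=False)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
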