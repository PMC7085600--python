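"""Readers, writers and configuration plumbing.

Traces travel as CSV with columns ``t, ax, ay, az`` (raw integer counts),
either one file per channel or a single file with an extra ``channel``
column.  Template databases, ground truth and reports are JSON; config
files are YAML or JSON mirroring the dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import CHANNELS, FOREARM, UPPERARM, SensorConfig, Trace
from .recognizer import RecognizerConfig, SessionReport, process_stream
from .synthetic import SessionGroundTruth, ThrowGroundTruth, ThrowProfile
from .templates import TemplateDB, builtin_db, load_db

_TRACE_COLUMNS = ["t", "ax", "ay", "az"]


def _frame_to_trace(df: pd.DataFrame, channel: str, path) -> Trace:
    for col in _TRACE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    counts = df[["ax", "ay", "az"]].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError(f"{path}: axis columns must be numeric")
    bad = np.flatnonzero(np.any(np.abs(counts) > 32768, axis=1))
    if bad.size:
        raise ValueError(f"{path}: count out of range at row {int(bad[0])}")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: timestamps not monotone ({channel})")
    return Trace(t=t, counts=counts.astype(np.int32), channel=channel)


def read_trace(path, upper_path=None) -> tuple[Trace, Trace]:
    """Read both channels from one session CSV or from two per-channel CSVs."""
    df = pd.read_csv(path)
    if upper_path is not None:
        df_u = pd.read_csv(upper_path)
        return (
            _frame_to_trace(df, FOREARM, path),
            _frame_to_trace(df_u, UPPERARM, upper_path),
        )
    if "channel" not in df.columns:
        raise ValueError(
            f"{path}: single-file dialect requires a 'channel' column "
            "(or pass the upper-arm file separately)"
        )
    traces = {}
    for channel, sub in df.groupby("channel", sort=False):
        if channel not in CHANNELS:
            raise ValueError(f"{path}: unknown channel {channel!r}")
        traces[channel] = _frame_to_trace(sub.reset_index(drop=True), channel, path)
    for channel in CHANNELS:
        if channel not in traces:
            raise ValueError(f"{path}: channel {channel!r} missing")
    return traces[FOREARM], traces[UPPERARM]


def write_trace(forearm: Trace, upper: Trace, path, upper_path=None) -> None:
    """Write traces as CSV; single-file dialect when only one path is given."""
    def frame(tr: Trace) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": tr.t, "ax": tr.counts[:, 0], "ay": tr.counts[:, 1], "az": tr.counts[:, 2]}
        )

    if upper_path is not None:
        frame(forearm).to_csv(path, index=False)
        frame(upper).to_csv(upper_path, index=False)
        return
    df_f = frame(forearm)
    df_f.insert(0, "channel", FOREARM)
    df_u = frame(upper)
    df_u.insert(0, "channel", UPPERARM)
    pd.concat([df_f, df_u], ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ground truth JSON


def write_ground_truth(truth: SessionGroundTruth | ThrowGroundTruth, path) -> None:
    if isinstance(truth, ThrowGroundTruth):
        truth = SessionGroundTruth(throws=[truth], offsets=[0])
    payload = {
        "offsets": list(truth.offsets),
        "throws": [
            {
                "error_id": gt.error_id,
                "onset": int(gt.onset),
                "end": int(gt.end),
                "step_bounds": {str(k): list(v) for k, v in gt.step_bounds.items()},
                "intended": {str(k): list(v) for k, v in gt.intended.items()},
                "profile": dataclasses.asdict(gt.profile),
                "levels_forearm": gt.levels_forearm.tolist(),
                "levels_upper": gt.levels_upper.tolist(),
            }
            for gt in truth.throws
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> SessionGroundTruth:
    payload = json.loads(Path(path).read_text())
    throws = []
    for d in payload["throws"]:
        prof = d["profile"]
        prof["step_durations"] = tuple(prof["step_durations"])
        throws.append(
            ThrowGroundTruth(
                levels_forearm=np.asarray(d["levels_forearm"], dtype=np.int8),
                levels_upper=np.asarray(d["levels_upper"], dtype=np.int8),
                step_bounds={int(k): tuple(v) for k, v in d["step_bounds"].items()},
                intended={int(k): tuple(v) for k, v in d["intended"].items()},
                onset=d["onset"],
                end=d["end"],
                error_id=d["error_id"],
                profile=ThrowProfile(**prof),
            )
        )
    return SessionGroundTruth(throws=throws, offsets=list(payload["offsets"]))


# ---------------------------------------------------------------------------
# configuration


def _build_config(data: dict, cls):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key {sorted(unknown)[0]!r} for {cls.__name__}")
    kwargs = dict(data)
    for key in ("step_durations", "standing_forearm", "standing_upperarm"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path) -> dict:
    """Load a YAML/JSON config file into plain nested dicts."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def configs_from_dict(data: dict) -> tuple[SensorConfig, RecognizerConfig]:
    """Build sensor and recognizer configs from a config mapping.

    Accepts either nested sections (``sensor:``, ``recognizer:``) or a flat
    mapping of SensorConfig field names (the on-disk sensor-config dialect).
    """
    reserved = {"sensor", "recognizer", "templates", "trace", "trace_upper"}
    body = {k: v for k, v in data.items() if k not in reserved}
    if "sensor" in data or "recognizer" in data:
        if body:
            raise ValueError(f"unknown config key {sorted(body)[0]!r}")
        sensor = _build_config(data.get("sensor", {}), SensorConfig)
        rec = _build_config(data.get("recognizer", {}), RecognizerConfig)
        return sensor, rec
    return _build_config(body, SensorConfig), RecognizerConfig()


def write_report(report, path) -> None:
    """Serialize a SessionReport or AccuracyReport deterministically to JSON."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# pipeline front door


def run_pipeline(config: dict) -> SessionReport:
    """Read -> preprocess -> encode -> recognize from a config mapping.

    Required key: ``trace`` (session CSV, or forearm CSV with
    ``trace_upper``).  Optional: ``templates`` (JSON DB path), ``sensor``
    and ``recognizer`` sections.
    """
    if "trace" not in config:
        raise ValueError("config key 'trace' is required")
    sensor, rec = configs_from_dict(config)
    db: TemplateDB = load_db(config["templates"]) if config.get("templates") else builtin_db()
    forearm, upper = read_trace(config["trace"], config.get("trace_upper"))
    return process_stream(forearm, upper, db, sensor, rec)
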