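"""File formats: WAV signals with JSON sidecars, CSV tables.

Conventions: flow signals are written as 32-bit float WAV (one channel,
values in L/s) with a ``<name>.json`` sidecar recording the unit and
sample rate; /pa/ utterances as 2-channel float WAV (intraoral pressure
Pa, oral flow L/s) plus JSON segment labels; feature and dataset tables
as CSV with the exact canonical column names.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .features import FEATURE_NAMES, ZScoreStats
from .params import PARAM_NAMES
from .source import SourceSignal, UtteranceChannels


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_signal_wav(signal: SourceSignal, path: str) -> None:
    """Write a flow signal as float32 WAV + JSON sidecar (rate, unit)."""
    wavfile.write(path, int(signal.sample_rate), signal.flow.astype(np.float32))
    meta = {
        "sample_rate": signal.sample_rate,
        "flow_unit": signal.flow_unit,
        "duration": signal.duration,
    }
    params = signal.meta.get("params")
    if params is not None:
        meta["params"] = dict(zip(PARAM_NAMES, params.to_array().tolist()))
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_signal_wav(path: str) -> SourceSignal:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected a single-channel flow WAV")
    unit = "L/s"
    side = _sidecar(path)
    if side.exists():
        unit = json.loads(side.read_text()).get("flow_unit", unit)
    return SourceSignal.from_flow(data.astype(float), float(rate), unit)


def write_utterance_wav(channels: UtteranceChannels, path: str) -> None:
    """Write pressure+flow as a 2-channel float32 WAV + JSON labels sidecar."""
    stereo = np.stack(
        [channels.intraoral_pressure, channels.oral_flow], axis=1
    ).astype(np.float32)
    wavfile.write(path, int(channels.sample_rate), stereo)
    _sidecar(path).write_text(
        json.dumps(
            {
                "sample_rate": channels.sample_rate,
                "channels": ["intraoral_pressure_Pa", "oral_flow_L_per_s"],
                "segment_labels": [
                    {"kind": k, "start": t0, "end": t1}
                    for k, t0, t1 in channels.segment_labels
                ],
            },
            indent=2,
        )
    )


def read_utterance_wav(path: str) -> UtteranceChannels:
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected a 2-channel (pressure, flow) WAV")
    labels: List[Tuple[str, float, float]] = []
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        labels = [
            (d["kind"], float(d["start"]), float(d["end"]))
            for d in meta.get("segment_labels", [])
        ]
    return UtteranceChannels(
        intraoral_pressure=data[:, 0].astype(float),
        oral_flow=data[:, 1].astype(float),
        sample_rate=float(rate),
        segment_labels=labels,
    )


def read_flow_csv(path: str, sample_rate: Optional[float] = None) -> SourceSignal:
    """Read a flow signal from CSV with columns ``time`` (s) and ``flow`` (L/s)
    — or a single ``flow`` column plus an explicit ``sample_rate``."""
    df = pd.read_csv(path)
    if "flow" not in df.columns:
        raise ValueError(f"{path}: missing required column 'flow'")
    if sample_rate is None:
        if "time" not in df.columns:
            raise ValueError(f"{path}: need a 'time' column or an explicit sample rate")
        dt = np.diff(df["time"].to_numpy())
        if len(dt) < 1 or np.std(dt) > 1e-6 * np.mean(dt):
            raise ValueError(f"{path}: time column must be uniformly sampled")
        sample_rate = 1.0 / float(np.mean(dt))
    return SourceSignal.from_flow(df["flow"].to_numpy(dtype=float), sample_rate)


def _read_table(path: str, required, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing {kind} columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    return df[list(required)]


def write_dataset(df: pd.DataFrame, path: str) -> None:
    """Write a 14+9-column feature/parameter table."""
    cols = [*FEATURE_NAMES, *PARAM_NAMES]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    df[cols].to_csv(path, index=False)


def read_dataset(path: str) -> pd.DataFrame:
    return _read_table(path, (*FEATURE_NAMES, *PARAM_NAMES), "dataset")


def write_features_csv(features_list, path: str) -> None:
    arr = np.array([f.to_array() for f in features_list])
    pd.DataFrame(arr, columns=list(FEATURE_NAMES)).to_csv(path, index=False)


def read_features_csv(path: str) -> np.ndarray:
    return _read_table(path, FEATURE_NAMES, "feature").to_numpy(dtype=float)


def write_predictions_csv(pred, path: str) -> None:
    """Write per-parameter mean and 95% bounds (``_lo95``/``_hi95`` suffixes)."""
    cols = {}
    for j, name in enumerate(PARAM_NAMES):
        cols[name] = pred.mean[:, j]
        cols[f"{name}_lo95"] = pred.lower[:, j]
        cols[f"{name}_hi95"] = pred.upper[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_zscore_stats(stats: ZScoreStats, path: str) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2))


def read_zscore_stats(path: str) -> ZScoreStats:
    return ZScoreStats.from_dict(json.loads(Path(path).read_text()))
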