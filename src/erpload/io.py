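"""Readers and writers for continuous EEG, event markers, and result tables.

Three on-disk formats are supported for continuous recordings, selected by
file extension:

``.edf``
    16-bit European Data Format (see :mod:`erpload._edf`); values are
    quantized to the 16-bit physical/digital mapping.
``.json``
    Native container: a JSON header next to a little-endian float32 binary
    sidecar (``<stem>.dat``).  Lossless up to float32.
``.csv``
    Plain text, one column per channel plus leading ``# key=value`` metadata
    lines.  Exact to the printed precision; intended for tiny fixtures.

Event markers, trial logs, questionnaires and amplitude tables are CSV with
fixed, documented column sets.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _edf
from .errors import ConfigError, DataValidationError

EVENT_COLUMNS = ["sample_index", "time_s", "label", "condition", "scheme", "trial_id"]
AMPLITUDE_COLUMNS = [
    "participant",
    "scheme",
    "condition",
    "component",
    "electrode",
    "amplitude_uv",
    "n_epochs",
]

CONDITION_ORDER = ("view", "easy", "hard")
SCHEME_ORDER = ("DC", "PRC")
COMPONENT_ORDER = ("N100", "P200", "P300", "LPP")


@dataclass
class ContinuousRecording:
    """Multi-channel microvolt time series with aligned metadata."""

    channel_labels: list[str]
    sfreq: float
    data: np.ndarray  # channels x samples, microvolts
    reference: str = "A1"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if len(self.channel_labels) == 0:
            raise ConfigError("recording needs at least one channel")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigError(f"duplicate channel labels: {self.channel_labels}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ConfigError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sfreq <= 0:
            raise ConfigError(f"sfreq must be positive, got {self.sfreq}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise DataValidationError(
                f"channel {label!r} not present; available: {self.channel_labels}"
            ) from None


@dataclass(order=True)
class EventMarker:
    """One probe onset, 0-based sample index into the recording."""

    sample_index: int
    label: str = field(compare=False)
    condition: str = field(compare=False)
    scheme: str = field(compare=False)
    trial_id: int = field(compare=False)


def write_recording(rec: ContinuousRecording, path: str | os.PathLike) -> None:
    """Write a recording; format chosen by extension (.edf, .json, .csv)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        _edf.write_edf(path, rec.data, rec.channel_labels, rec.sfreq, rec.start_time)
    elif suffix == ".json":
        sidecar = path.with_suffix(".dat")
        header = {
            "format": "erpload-container-v1",
            "channel_labels": rec.channel_labels,
            "sfreq": rec.sfreq,
            "reference": rec.reference,
            "start_time": rec.start_time,
            "n_samples": rec.n_samples,
            "dtype": "<f4",
            "data_file": sidecar.name,
        }
        path.write_text(json.dumps(header, indent=1, sort_keys=True) + "\n")
        rec.data.astype("<f4").tofile(sidecar)
    elif suffix == ".csv":
        with open(path, "w") as fh:
            fh.write(f"# sfreq={rec.sfreq:.17g}\n")
            fh.write(f"# reference={rec.reference}\n")
            fh.write(f"# start_time={rec.start_time:.17g}\n")
            fh.write(",".join(rec.channel_labels) + "\n")
            np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")
    else:
        raise ConfigError(f"unknown recording format for {path.name!r} "
                          "(expected .edf, .json, or .csv)")


def read_recording(path: str | os.PathLike) -> ContinuousRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".edf":
        data, labels, sfreq, start_time = _edf.read_edf(path)
        return ContinuousRecording(labels, sfreq, data, start_time=start_time)
    if suffix == ".json":
        header = json.loads(path.read_text())
        if header.get("format") != "erpload-container-v1":
            raise DataValidationError(f"{path}: not an erpload container header")
        sidecar = path.parent / header["data_file"]
        if not sidecar.exists():
            raise DataValidationError(f"{path}: missing data sidecar {sidecar.name}")
        n_ch = len(header["channel_labels"])
        n_samples = int(header["n_samples"])
        raw = np.fromfile(sidecar, dtype=header["dtype"])
        if raw.size != n_ch * n_samples:
            raise DataValidationError(
                f"{sidecar}: has {raw.size} values, header promises {n_ch * n_samples}"
            )
        return ContinuousRecording(
            list(header["channel_labels"]),
            float(header["sfreq"]),
            raw.reshape(n_ch, n_samples).astype(float),
            reference=header.get("reference", "A1"),
            start_time=float(header.get("start_time", 0.0)),
        )
    if suffix == ".csv":
        meta: dict[str, str] = {}
        with open(path) as fh:
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                line = fh.readline()
            labels = [c.strip() for c in line.strip().split(",")]
            body = np.loadtxt(fh, delimiter=",", ndmin=2)
        if "sfreq" not in meta:
            raise DataValidationError(f"{path}: missing '# sfreq=' metadata line")
        return ContinuousRecording(
            labels,
            float(meta["sfreq"]),
            body.T,
            reference=meta.get("reference", "A1"),
            start_time=float(meta.get("start_time", 0.0)),
        )
    raise ConfigError(f"unknown recording format for {path.name!r}")


def write_events(events: Sequence[EventMarker], path: str | os.PathLike, sfreq: float) -> None:
    rows = [
        {
            "sample_index": ev.sample_index,
            "time_s": ev.sample_index / sfreq,
            "label": ev.label,
            "condition": ev.condition,
            "scheme": ev.scheme,
            "trial_id": ev.trial_id,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | os.PathLike, n_samples: int | None = None) -> list[EventMarker]:
    """Read event markers, sorted ascending and optionally range-checked."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "time_s"]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")
    events: list[EventMarker] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        idx = int(row.sample_index)
        if idx < 0 or (n_samples is not None and idx >= n_samples):
            raise DataValidationError(
                f"{path} row {row_number}: sample_index {idx} out of range "
                f"[0, {n_samples})"
            )
        events.append(
            EventMarker(
                sample_index=idx,
                label=str(row.label),
                condition=str(row.condition),
                scheme=str(row.scheme),
                trial_id=int(row.trial_id),
            )
        )
    events.sort()
    return events


def _sort_key(row: dict) -> tuple:
    def rank(value, order):
        return order.index(value) if value in order else len(order)

    return (
        row["participant"],
        rank(row["scheme"], SCHEME_ORDER),
        rank(row["condition"], CONDITION_ORDER),
        rank(row["component"], COMPONENT_ORDER),
        row["electrode"],
    )


def write_amplitude_table(records: Iterable, path: str | os.PathLike) -> None:
    """Write AmplitudeRecords as a long-format CSV with a deterministic order.

    Duplicate (participant, scheme, condition, component, electrode) keys are
    rejected.
    """
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            rows.append({c: rec[c] for c in AMPLITUDE_COLUMNS})
        else:
            rows.append({c: getattr(rec, c) for c in AMPLITUDE_COLUMNS})
    keys = [tuple(r[c] for c in AMPLITUDE_COLUMNS[:5]) for r in rows]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise DataValidationError(f"duplicate amplitude-table keys: {dupes[:5]}")
    rows.sort(key=_sort_key)
    pd.DataFrame(rows, columns=AMPLITUDE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_amplitude_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in AMPLITUDE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing amplitude-table columns {missing}")
    return df


def write_trial_log(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_trial_log(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "scheme", "condition", "trial_id", "success", "duration_s"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing trial-log columns {sorted(missing)}")
    return df


def write_questionnaires(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def read_questionnaires(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "scheme"} | {f"q{i}" for i in range(1, 8)}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing questionnaire columns {sorted(missing)}")
    return df
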