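"""Continuous EEG -> clean, baseline-corrected probe epochs.

Conventions (used consistently across the package):

* epochs span ``[tmin, tmax]`` ms inclusive of both endpoint samples at the
  native rate (1101 samples for -100..1000 ms at 1000 Hz);
* the baseline interval is ``[-100, 0)`` ms — the probe-onset sample is
  excluded;
* the band-pass is a 4th-order Butterworth applied forward-backward, so the
  output is zero-phase and event-locked latencies are not shifted;
* artifact rejection is an automated stand-in for visual inspection:
  an epoch is flagged when any EOG channel exceeds ``eog_p2p`` microvolts
  peak-to-peak or any EEG channel exceeds ``eeg_abs`` microvolts absolute.
"""

from __future__ import annotations

import io as _stdlib_io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, DataValidationError
from .io import ContinuousRecording, EventMarker
from .simulate import EOG_LABELS

KEY_COLUMNS = ["participant", "scheme", "condition", "trial_id", "probe_index", "sample_index"]


@dataclass
class EpochSet:
    """Per-probe EEG segments with bookkeeping for rejection and drops."""

    epochs: np.ndarray  # n_epochs x n_channels x n_samples, microvolts
    times: np.ndarray  # ms relative to probe onset
    channel_labels: list[str]
    keys: pd.DataFrame  # one row per epoch, KEY_COLUMNS
    artifact_flags: np.ndarray  # bool per epoch
    artifact_reasons: list[str]  # "" when clean
    dropped: list[dict] = field(default_factory=list)  # events with no full window
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.epochs.shape[0]
        if not (len(self.keys) == n == len(self.artifact_flags) == len(self.artifact_reasons)):
            raise DataValidationError("epoch bookkeeping arrays disagree in length")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def sfreq(self) -> float:
        if len(self.times) < 2:
            raise DataValidationError("times axis too short to infer sfreq")
        return 1000.0 / float(self.times[1] - self.times[0])

    def clean_mask(self) -> np.ndarray:
        return ~self.artifact_flags

    def clean_counts(self) -> dict[tuple[str, str], int]:
        """Clean-epoch count per (scheme, condition) cell."""
        out: dict[tuple[str, str], int] = {}
        clean = self.keys[self.clean_mask()]
        for (scheme, condition), grp in clean.groupby(["scheme", "condition"], sort=True):
            out[(str(scheme), str(condition))] = len(grp)
        return out

    def select(self, **criteria) -> "EpochSet":
        """Subset by key-column equality, e.g. ``select(condition="hard")``."""
        mask = np.ones(self.n_epochs, dtype=bool)
        for col, value in criteria.items():
            mask &= (self.keys[col] == value).to_numpy()
        idx = np.flatnonzero(mask)
        return EpochSet(
            epochs=self.epochs[idx],
            times=self.times,
            channel_labels=self.channel_labels,
            keys=self.keys.iloc[idx].reset_index(drop=True),
            artifact_flags=self.artifact_flags[idx],
            artifact_reasons=[self.artifact_reasons[i] for i in idx],
            dropped=self.dropped,
            warnings=self.warnings,
        )


@dataclass(frozen=True)
class InclusionDecision:
    """Whether a participant has >= min_trials clean epochs in every cell."""

    participant: int
    counts: Mapping[tuple[str, str], int]
    min_trials: int
    included: bool
    warnings: tuple[str, ...] = ()


def bandpass_filter(
    rec: ContinuousRecording, low: float = 1.0, high: float = 15.0, order: int = 4
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass of a continuous recording."""
    nyquist = rec.sfreq / 2.0
    if not 0 < low < high:
        raise ConfigError(f"need 0 < low < high, got {low}, {high}")
    if high >= nyquist:
        raise ConfigError(f"high edge {high} Hz >= Nyquist {nyquist} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sfreq, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return ContinuousRecording(
        list(rec.channel_labels),
        rec.sfreq,
        filtered,
        reference=rec.reference,
        start_time=rec.start_time,
    )


def extract_epochs(
    rec: ContinuousRecording,
    events: Sequence[EventMarker],
    participant: int,
    tmin: float = -100.0,
    tmax: float = 1000.0,
) -> EpochSet:
    """Cut ``[tmin, tmax]`` ms windows (inclusive endpoints) around each event.

    Events whose window would leave the recording are dropped and logged in
    ``EpochSet.dropped`` rather than padded.
    """
    if tmin >= tmax:
        raise ConfigError(f"tmin {tmin} must be < tmax {tmax}")
    sfreq = rec.sfreq
    offset = int(round(tmin * sfreq / 1000.0))
    n_per = int(round((tmax - tmin) * sfreq / 1000.0)) + 1
    times = tmin + np.arange(n_per) * 1000.0 / sfreq

    kept: list[np.ndarray] = []
    keys: list[dict] = []
    dropped: list[dict] = []
    probe_counter: dict[tuple, int] = {}
    for ev in sorted(events):
        start = ev.sample_index + offset
        stop = start + n_per
        cell = (ev.scheme, ev.condition, ev.trial_id)
        probe_index = probe_counter.get(cell, 0)
        probe_counter[cell] = probe_index + 1
        if start < 0 or stop > rec.n_samples:
            dropped.append(
                {
                    "sample_index": ev.sample_index,
                    "scheme": ev.scheme,
                    "condition": ev.condition,
                    "trial_id": ev.trial_id,
                    "reason": "window outside recording",
                }
            )
            continue
        kept.append(rec.data[:, start:stop])
        keys.append(
            {
                "participant": participant,
                "scheme": ev.scheme,
                "condition": ev.condition,
                "trial_id": ev.trial_id,
                "probe_index": probe_index,
                "sample_index": ev.sample_index,
            }
        )
    epochs = (
        np.stack(kept) if kept else np.empty((0, len(rec.channel_labels), n_per))
    )
    return EpochSet(
        epochs=epochs,
        times=times,
        channel_labels=list(rec.channel_labels),
        keys=pd.DataFrame(keys, columns=KEY_COLUMNS),
        artifact_flags=np.zeros(len(kept), dtype=bool),
        artifact_reasons=[""] * len(kept),
        dropped=dropped,
    )


def baseline_correct(epochs: EpochSet, baseline: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract each epoch/channel's mean over ``[baseline[0], baseline[1])`` ms."""
    b0, b1 = baseline
    mask = (epochs.times >= b0 - 1e-9) & (epochs.times < b1 - 1e-9)
    if not mask.any():
        raise DataValidationError(
            f"no samples in baseline interval [{b0}, {b1}) ms; times start at "
            f"{epochs.times[0] if len(epochs.times) else 'n/a'} ms"
        )
    corrected = epochs.epochs - epochs.epochs[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, epochs=corrected)


def reject_artifacts(
    epochs: EpochSet, eog_p2p: float = 100.0, eeg_abs: float = 75.0
) -> EpochSet:
    """Flag epochs exceeding EOG peak-to-peak or EEG absolute thresholds.

    Flags are recomputed from scratch, so the operation is idempotent.  With
    no EOG channels present a warning is recorded and only the EEG criterion
    applies.
    """
    labels = epochs.channel_labels
    eog_idx = [i for i, lab in enumerate(labels) if lab.upper() in EOG_LABELS]
    eeg_idx = [i for i in range(len(labels)) if i not in eog_idx]
    warnings = [w for w in epochs.warnings if not w.startswith("reject_artifacts:")]
    if not eog_idx:
        warnings.append(
            "reject_artifacts: no EOG channels found; applying EEG criterion only"
        )
    flags = np.zeros(epochs.n_epochs, dtype=bool)
    reasons = [""] * epochs.n_epochs
    for i in range(epochs.n_epochs):
        why = []
        for c in eog_idx:
            p2p = float(np.ptp(epochs.epochs[i, c]))
            if p2p > eog_p2p:
                why.append(f"eog_p2p:{labels[c]}")
        for c in eeg_idx:
            if float(np.max(np.abs(epochs.epochs[i, c]))) > eeg_abs:
                why.append(f"eeg_abs:{labels[c]}")
        if why:
            flags[i] = True
            reasons[i] = ";".join(why)
    return replace(epochs, artifact_flags=flags, artifact_reasons=reasons, warnings=warnings)


def enforce_min_trials(
    counts: Mapping[tuple[str, str], int],
    participant: int,
    cells: Sequence[tuple[str, str]] | None = None,
    min_trials: int = 30,
) -> InclusionDecision:
    """Retain a participant iff every scheme x condition cell has enough clean epochs.

    ``cells`` lists the expected cells; a missing cell counts as 0 with a
    warning.
    """
    if cells is None:
        cells = sorted(counts.keys())
    if not cells:
        raise ConfigError("no scheme x condition cells to check")
    warnings = []
    filled: dict[tuple[str, str], int] = {}
    for cell in cells:
        if cell in counts:
            filled[cell] = int(counts[cell])
        else:
            filled[cell] = 0
            warnings.append(f"cell {cell} missing from counts; treated as 0")
    included = min(filled.values()) >= min_trials
    return InclusionDecision(
        participant=participant,
        counts=filled,
        min_trials=min_trials,
        included=included,
        warnings=tuple(warnings),
    )


def save_epochs(epochs: EpochSet, path) -> None:
    """Persist an EpochSet as a .npz bundle (arrays + key table)."""
    np.savez_compressed(
        path,
        epochs=epochs.epochs,
        times=epochs.times,
        channel_labels=np.array(epochs.channel_labels),
        artifact_flags=epochs.artifact_flags,
        artifact_reasons=np.array(epochs.artifact_reasons, dtype=object),
        keys_json=np.array(epochs.keys.to_json(orient="records")),
        dropped_json=np.array(pd.DataFrame(epochs.dropped).to_json(orient="records")),
        warnings=np.array(epochs.warnings, dtype=object),
    )


def load_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=True) as bundle:
        keys = pd.read_json(_stdlib_io.StringIO(str(bundle["keys_json"])))
        if keys.empty:
            keys = pd.DataFrame(columns=KEY_COLUMNS)
        dropped_df = pd.read_json(_stdlib_io.StringIO(str(bundle["dropped_json"])))
        return EpochSet(
            epochs=bundle["epochs"],
            times=bundle["times"],
            channel_labels=[str(c) for c in bundle["channel_labels"]],
            keys=keys[KEY_COLUMNS] if not keys.empty else keys,
            artifact_flags=bundle["artifact_flags"],
            artifact_reasons=[str(r) for r in bundle["artifact_reasons"]],
            dropped=dropped_df.to_dict(orient="records"),
            warnings=[str(w) for w in bundle["warnings"]],
        )


def rejection_log(epochs: EpochSet) -> pd.DataFrame:
    """One row per epoch with its artifact status, plus dropped events."""
    rows = epochs.keys.copy()
    rows["flagged"] = epochs.artifact_flags
    rows["reason"] = epochs.artifact_reasons
    return rows
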