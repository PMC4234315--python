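"""Condition averages, grand averages, peak finding, and window amplitudes.

Scoring windows default to the fixed list
N100 105-120 ms, P200 190-205 ms, P300 295-330 ms, LPP 570-590 ms, with both
endpoints included (endpoints are rounded to the nearest sample).  An
alternative mode re-centers each window on the grand-average peak found
inside a component-specific search range, preserving the window's width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataValidationError
from .preprocess import EpochSet


@dataclass
class ErpAverage:
    """Time-domain average for one participant x scheme x condition cell.

    ``participant`` is the string "grand" for across-participant averages.
    """

    participant: str
    scheme: str
    condition: str
    data: np.ndarray  # channels x samples, microvolts
    times: np.ndarray  # ms
    channel_labels: list[str]
    n_epochs: int

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise DataValidationError(
                f"electrode {label!r} absent; available: {self.channel_labels}"
            ) from None
        return self.data[idx]


@dataclass(frozen=True)
class ComponentWindow:
    component: str
    start_ms: float
    end_ms: float
    electrodes: tuple[str, ...]
    polarity: str  # "negative" | "positive"

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ConfigError(f"{self.component}: window start must precede end")
        if self.polarity not in ("negative", "positive"):
            raise ConfigError(f"{self.component}: bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class AmplitudeRecord:
    participant: object
    scheme: str
    condition: str
    component: str
    electrode: str
    amplitude_uv: float
    n_epochs: int


@dataclass(frozen=True)
class PeakResult:
    latency_ms: float
    amplitude_uv: float
    flagged: bool  # True when no distinct extremum exists in the range


def default_windows() -> list[ComponentWindow]:
    """The fixed analysis windows at their analysis electrodes."""
    return [
        ComponentWindow("N100", 105.0, 120.0, ("Cz",), "negative"),
        ComponentWindow("P200", 190.0, 205.0, ("Fz", "Cz", "Pz"), "positive"),
        ComponentWindow("P300", 295.0, 330.0, ("Pz",), "positive"),
        ComponentWindow("LPP", 570.0, 590.0, ("Pz",), "positive"),
    ]


# search ranges for the recentering mode: (start_ms, end_ms, electrode)
PEAK_SEARCH_RANGES: dict[str, tuple[float, float, str]] = {
    "N100": (80.0, 160.0, "Cz"),
    "P200": (150.0, 250.0, "Cz"),
    "P300": (250.0, 450.0, "Pz"),
    "LPP": (450.0, 800.0, "Pz"),
}


def average_epochs(
    epochs: EpochSet,
    participant: object,
    scheme: str,
    condition: str,
    min_trials: int = 30,
) -> ErpAverage:
    """Pointwise mean over the clean epochs of one cell.

    Refuses cells below ``min_trials`` clean epochs — such participants belong
    in the exclusion list, not the averages.
    """
    cell = epochs.select(scheme=scheme, condition=condition)
    clean = cell.epochs[cell.clean_mask()]
    if len(clean) < min_trials:
        raise DataValidationError(
            f"cell participant={participant} scheme={scheme} condition={condition} "
            f"has {len(clean)} clean epochs < min_trials={min_trials}; see the "
            "InclusionDecision for this participant"
        )
    return ErpAverage(
        participant=str(participant),
        scheme=scheme,
        condition=condition,
        data=clean.mean(axis=0),
        times=epochs.times.copy(),
        channel_labels=list(epochs.channel_labels),
        n_epochs=len(clean),
    )


def grand_average(averages: Sequence[ErpAverage]) -> ErpAverage:
    """Unweighted mean across participant averages (equal weight per participant)."""
    if len(averages) < 2:
        raise ConfigError("grand average needs at least 2 participant averages")
    first = averages[0]
    for avg in averages[1:]:
        if len(avg.times) != len(first.times) or not np.allclose(avg.times, first.times):
            raise DataValidationError("mismatched times axes across participant averages")
        if avg.channel_labels != first.channel_labels:
            raise DataValidationError("mismatched channel labels across participant averages")
    return ErpAverage(
        participant="grand",
        scheme=first.scheme,
        condition=first.condition,
        data=np.mean([a.data for a in averages], axis=0),
        times=first.times.copy(),
        channel_labels=list(first.channel_labels),
        n_epochs=sum(a.n_epochs for a in averages),
    )


def find_peak(
    erp: ErpAverage,
    electrode: str,
    search_range: tuple[float, float],
    polarity: str,
) -> PeakResult:
    """Latency of the extremum of the stated polarity inside ``search_range``.

    Ties break to the earliest latency; a flat trace returns the range start
    flagged as having no distinct peak.
    """
    lo, hi = search_range
    mask = (erp.times >= lo - 1e-9) & (erp.times <= hi + 1e-9)
    if not mask.any():
        raise ConfigError(f"search range {search_range} outside epoch times axis")
    trace = erp.channel(electrode)[mask]
    times = erp.times[mask]
    signed = -trace if polarity == "negative" else trace
    idx = int(np.argmax(signed))  # argmax returns the first maximum: earliest tie-break
    flat = bool(np.all(signed == signed[0]))
    if flat:
        idx = 0
    return PeakResult(
        latency_ms=float(times[idx]),
        amplitude_uv=float(trace[idx]),
        flagged=flat,
    )


def recenter_windows(
    grand_averages: Sequence[ErpAverage],
    windows: Sequence[ComponentWindow] | None = None,
) -> list[ComponentWindow]:
    """Re-center each window about the grand-average peak, preserving its width.

    The peak is searched in the pooled mean of the supplied grand averages
    (typically one per condition) at the component's search electrode.
    """
    if windows is None:
        windows = default_windows()
    pooled = grand_average(list(grand_averages)) if len(grand_averages) > 1 else grand_averages[0]
    out = []
    for window in windows:
        lo, hi, electrode = PEAK_SEARCH_RANGES[window.component]
        peak = find_peak(pooled, electrode, (lo, hi), window.polarity)
        half = (window.end_ms - window.start_ms) / 2.0
        out.append(
            replace(window, start_ms=peak.latency_ms - half, end_ms=peak.latency_ms + half)
        )
    return out


def window_mean(erp: ErpAverage, window: ComponentWindow, electrode: str) -> AmplitudeRecord:
    """Mean amplitude over the window (endpoints inclusive) at one electrode."""
    sfreq = 1000.0 / float(erp.times[1] - erp.times[0])
    i0 = int(round((window.start_ms - erp.times[0]) * sfreq / 1000.0))
    i1 = int(round((window.end_ms - erp.times[0]) * sfreq / 1000.0))
    if i0 < 0 or i1 >= len(erp.times):
        raise ConfigError(
            f"window {window.start_ms}-{window.end_ms} ms outside epoch "
            f"({erp.times[0]}-{erp.times[-1]} ms)"
        )
    trace = erp.channel(electrode)
    return AmplitudeRecord(
        participant=erp.participant,
        scheme=erp.scheme,
        condition=erp.condition,
        component=window.component,
        electrode=electrode,
        amplitude_uv=float(trace[i0 : i1 + 1].mean()),
        n_epochs=erp.n_epochs,
    )


def score_averages(
    averages: Iterable[ErpAverage],
    windows: Sequence[ComponentWindow] | None = None,
    electrodes: Sequence[str] | None = None,
) -> list[AmplitudeRecord]:
    """Window means for every average x component x electrode combination.

    ``electrodes`` overrides each window's own electrode list (used when the
    full Fz/Cz/Pz table is wanted for all components).
    """
    if windows is None:
        windows = default_windows()
    records = []
    for avg in averages:
        for window in windows:
            sites = tuple(electrodes) if electrodes is not None else window.electrodes
            for electrode in sites:
                records.append(window_mean(avg, window, electrode))
    return records
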