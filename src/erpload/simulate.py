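"""Seeded, ground-truth-known session generator.

Produces everything the analysis pipeline consumes for one simulated study:
counterbalanced session schedules, per-trial behavior logs, irrelevant-probe
event times, Likert questionnaires, and continuous multi-channel EEG in
microvolts with known injected ERP component amplitudes.

The rendered signal is a sum of independent parts::

    signal = pink(1/f) background
           + shared 10 Hz alpha oscillation (posterior-weighted)
           + per-probe ERP templates (raised-cosine bumps, polarity-signed,
             scaled by base_amplitude x attenuation(condition) [+ scheme
             offset in the hard condition] x participant factor x channel
             topography weight)
           + eyeblink transients (large slow half-cosines, maximal on VEOG
             with frontal spread)

so that rendering is linear in the component list and every injected quantity
can be returned as ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ContinuousRecording, EventMarker

EOG_LABELS = ("VEOG", "HEOG")

# purpose codes for child-seed derivation; never reorder (breaks determinism)
_SEED_BEHAVIOR = 0
_SEED_PROBES = 1
_SEED_NOISE = 2
_SEED_BLINKS = 3
_SEED_AMP_FACTOR = 4
_SEED_QUESTIONNAIRE = 5
_SEED_COHORT = 6


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def _component_code(name: str) -> int:
    return zlib.crc32(name.encode())


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    """Study-level layout and acquisition parameters."""

    n_participants: int = 18
    schemes: tuple[str, ...] = ("DC", "PRC")
    conditions: tuple[str, ...] = ("view", "easy", "hard")
    trials_easy_per_dof: int = 24
    n_dofs: int = 3
    trials_hard: int = 32
    trials_view: int = 32
    probe_min: int = 0
    probe_max: int = 3
    min_probe_separation: float = 1.5
    trial_timeout: float = 24.0
    planning_delay: float = 4.0
    inter_trial_gap: float = 1.0
    allow_planning_probes: bool = False
    sfreq: float = 1000.0
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz", "VEOG", "HEOG")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not self.schemes or not self.conditions:
            raise ConfigError("schemes and conditions must be non-empty")
        if self.probe_min > self.probe_max or self.probe_min < 0:
            raise ConfigError(
                f"need 0 <= probe_min <= probe_max, got {self.probe_min}..{self.probe_max}"
            )
        if self.trial_timeout <= 0:
            raise ConfigError("trial_timeout must be positive")
        if self.sfreq <= 0:
            raise ConfigError("sfreq must be positive")
        if self.min_probe_separation <= 0:
            raise ConfigError("min_probe_separation must be positive")

    @property
    def eeg_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c not in EOG_LABELS)


@dataclass(frozen=True)
class ComponentSpec:
    """Generative description of one ERP component.

    ``half_width`` is the full width at half maximum of the raised-cosine
    template (total support is twice that).  ``attenuation`` maps condition ->
    multiplicative factor; ``scheme_delta`` maps scheme -> additive microvolt
    offset applied in the hard condition only.
    """

    name: str
    polarity: str  # "negative" | "positive"
    peak_latency: float  # ms after probe onset
    half_width: float  # ms, FWHM
    topography: Mapping[str, float]
    base_amplitude: float  # microvolts
    attenuation: Mapping[str, float]
    scheme_delta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ConfigError(f"{self.name}: polarity must be negative|positive")
        if self.half_width <= 0 or self.base_amplitude < 0:
            raise ConfigError(f"{self.name}: half_width and base_amplitude must be positive")
        for cond, a in self.attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ConfigError(f"{self.name}: attenuation[{cond}]={a} outside [0, 1]")

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "negative" else 1.0

    def amplitude(self, scheme: str, condition: str) -> float:
        """Unsigned injected magnitude (before participant factor/topography)."""
        amp = self.base_amplitude * self.attenuation[condition]
        if condition == "hard":
            amp += self.scheme_delta.get(scheme, 0.0)
        return max(amp, 0.0)

    def waveform(self, times_ms: np.ndarray, amplitude: float) -> np.ndarray:
        """Signed template sampled at ``times_ms`` (ms relative to probe onset)."""
        support = 2.0 * self.half_width
        u = (np.asarray(times_ms, dtype=float) - self.peak_latency) / support
        out = np.zeros_like(u)
        inside = np.abs(u) <= 0.5
        out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[inside]))
        return self.sign * amplitude * out


def default_components() -> list[ComponentSpec]:
    """Component set whose amplitudes fall with task difficulty (except N100)."""
    return [
        ComponentSpec(
            name="N100",
            polarity="negative",
            peak_latency=112.0,
            half_width=40.0,
            topography={"Fz": 0.8, "Cz": 1.0, "Pz": 0.6},
            base_amplitude=5.0,
            attenuation={"view": 1.0, "easy": 1.0, "hard": 1.0},
        ),
        ComponentSpec(
            name="P200",
            polarity="positive",
            peak_latency=198.0,
            half_width=30.0,
            topography={"Fz": 0.7, "Cz": 1.0, "Pz": 0.8},
            base_amplitude=6.0,
            attenuation={"view": 1.0, "easy": 0.65, "hard": 0.35},
        ),
        ComponentSpec(
            name="P300",
            polarity="positive",
            peak_latency=312.0,
            half_width=40.0,
            topography={"Fz": 0.35, "Cz": 0.45, "Pz": 1.0},
            base_amplitude=8.0,
            attenuation={"view": 1.0, "easy": 0.6, "hard": 0.25},
        ),
        ComponentSpec(
            name="LPP",
            polarity="positive",
            peak_latency=580.0,
            half_width=80.0,
            topography={"Fz": 0.25, "Cz": 0.35, "Pz": 1.0},
            base_amplitude=4.0,
            attenuation={"view": 1.0, "easy": 0.7, "hard": 0.4},
            scheme_delta={"PRC": 0.8},
        ),
    ]


def null_components() -> list[ComponentSpec]:
    """Same components with condition/scheme effects removed (for calibration)."""
    return [
        replace(c, attenuation={k: 1.0 for k in c.attenuation}, scheme_delta={})
        for c in default_components()
    ]


@dataclass(frozen=True)
class BehaviorCell:
    success_probability: float
    completion_time_mean: float
    completion_time_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_probability <= 1.0:
            raise ConfigError(f"success_probability {self.success_probability} outside [0, 1]")
        if self.completion_time_mean <= 0 or self.completion_time_sd < 0:
            raise ConfigError("completion time mean must be > 0 and sd >= 0")


@dataclass(frozen=True)
class BehaviorParams:
    """Per scheme x condition trial-outcome law (view has no behavior)."""

    cells: Mapping[tuple[str, str], BehaviorCell]

    def cell(self, scheme: str, condition: str) -> BehaviorCell:
        try:
            return self.cells[(scheme, condition)]
        except KeyError:
            raise ConfigError(
                f"no behavior parameters for scheme={scheme!r}, condition={condition!r}"
            ) from None


def default_behavior() -> BehaviorParams:
    # completion-time means/SDs follow the reported cell statistics; success
    # probabilities are free simulation parameters (no significant DC/PRC
    # difference, easy near ceiling)
    return BehaviorParams(
        cells={
            ("DC", "easy"): BehaviorCell(0.97, 2.4, 0.81),
            ("PRC", "easy"): BehaviorCell(0.97, 2.8, 0.81),
            ("DC", "hard"): BehaviorCell(0.85, 15.1, 2.18),
            ("PRC", "hard"): BehaviorCell(0.88, 12.5, 2.19),
        }
    )


@dataclass(frozen=True)
class NoiseParams:
    """Background/artifact model for the rendered EEG."""

    pink_rms: float = 6.0  # microvolts, per channel
    alpha_amplitude: float = 3.0  # microvolts at the Pz weight
    alpha_freq: float = 10.0
    alpha_weights: Mapping[str, float] = field(
        default_factory=lambda: {"Fz": 0.3, "Cz": 0.6, "Pz": 1.0}
    )
    blink_rate_per_min: float = 8.0
    blink_amplitude: float = 150.0  # microvolts on VEOG
    blink_duration: float = 0.4  # seconds
    blink_weights: Mapping[str, float] = field(
        default_factory=lambda: {"VEOG": 1.0, "HEOG": 0.1, "Fz": 0.4, "Cz": 0.15, "Pz": 0.05}
    )
    participant_amp_sd: float = 0.15  # lognormal sigma of per-participant scaling

    def silent(self) -> "NoiseParams":
        return replace(
            self,
            pink_rms=0.0,
            alpha_amplitude=0.0,
            blink_rate_per_min=0.0,
            participant_amp_sd=0.0,
        )


# ---------------------------------------------------------------------------
# scheduling
# ---------------------------------------------------------------------------


@dataclass
class ParticipantSchedule:
    participant: int
    scheme_order: tuple[str, ...]
    condition_order: tuple[str, ...]
    # blocks: ordered (scheme, condition, trial descriptors)
    blocks: list[tuple[str, str, list[dict]]]


def _condition_trials(config: SessionConfig, condition: str) -> list[dict]:
    if condition == "easy":
        trials = []
        for dof in range(1, config.n_dofs + 1):
            trials += [{"dof": f"dof{dof}"} for _ in range(config.trials_easy_per_dof)]
        return trials
    n = config.trials_view if condition == "view" else config.trials_hard
    return [{"dof": f"{config.n_dofs}dof"} for _ in range(n)]


def build_schedule(config: SessionConfig) -> tuple[list[ParticipantSchedule], list[str]]:
    """Counterbalanced per-participant block orders.

    View is first for exactly half of an even cohort (half of each
    scheme-order stratum, up to parity); easy always precedes hard.  Returns
    ``(schedules, warnings)``; an odd cohort gets a documented remainder
    assignment plus a warning record.
    """
    warnings: list[str] = []
    if config.n_participants % 2:
        warnings.append(
            f"odd cohort size {config.n_participants}: last participant assigned "
            "the first combination in the cycle (DC-first, view-first); "
            "counterbalancing is approximate"
        )
    schemes = config.schemes
    # cycle chosen so both factors hit an exact 50/50 split for any even n
    combos = [
        (schemes, True),
        (tuple(reversed(schemes)), False),
        (tuple(reversed(schemes)), True),
        (schemes, False),
    ]
    schedules = []
    for p in range(config.n_participants):
        scheme_order, view_first = combos[p % 4]
        condition_order = ("view", "easy", "hard") if view_first else ("easy", "hard", "view")
        condition_order = tuple(c for c in condition_order if c in config.conditions)
        blocks = [
            (scheme, cond, _condition_trials(config, cond))
            for scheme in scheme_order
            for cond in condition_order
        ]
        schedules.append(ParticipantSchedule(p, scheme_order, condition_order, blocks))
    return schedules, warnings


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def _lognormal_time(rng: np.random.Generator, cell: BehaviorCell, timeout: float) -> float:
    m, s = cell.completion_time_mean, cell.completion_time_sd
    if s == 0.0:
        return min(m, timeout)
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    for _ in range(100):
        t = float(rng.lognormal(mu, sigma))
        if t < timeout:
            return t
    return timeout * (1.0 - 1e-9)


def simulate_behavior(
    schedules: Sequence[ParticipantSchedule],
    params: BehaviorParams,
    config: SessionConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-trial outcomes and lay each session out on a timeline.

    One timeline per participant x scheme (one recording each).  Columns:
    participant, scheme, condition, dof, trial_id, success, duration_s,
    t_cue, t_go, t_end.  View trials replay the hard task, so their durations
    are drawn from the hard cell of the same scheme with success left as NA.
    """
    if seed is None:
        seed = config.seed
    for scheme in config.schemes:
        for condition in config.conditions:
            if condition != "view":
                params.cell(scheme, condition)  # raises naming the missing cell
    rows = []
    for sched in schedules:
        for s_idx, scheme in enumerate(sched.scheme_order):
            rng = _rng(seed, _SEED_BEHAVIOR, sched.participant, s_idx)
            cursor = 0.0
            trial_id = 0
            for blk_scheme, condition, trials in sched.blocks:
                if blk_scheme != scheme:
                    continue
                for trial in trials:
                    if condition == "view":
                        cell = params.cell(scheme, "hard") if "hard" in config.conditions else None
                        success: object = np.nan
                        if cell is None:
                            duration = config.trial_timeout / 2.0
                        elif rng.uniform() < cell.success_probability:
                            duration = _lognormal_time(rng, cell, config.trial_timeout)
                        else:
                            duration = config.trial_timeout
                    else:
                        cell = params.cell(scheme, condition)
                        success = bool(rng.uniform() < cell.success_probability)
                        if success:
                            duration = _lognormal_time(rng, cell, config.trial_timeout)
                        else:
                            duration = config.trial_timeout
                    t_cue = cursor + config.inter_trial_gap
                    t_go = t_cue + config.planning_delay
                    t_end = t_go + duration
                    cursor = t_end
                    rows.append(
                        {
                            "participant": sched.participant,
                            "scheme": scheme,
                            "condition": condition,
                            "dof": trial["dof"],
                            "trial_id": trial_id,
                            "success": success,
                            "duration_s": duration,
                            "t_cue": t_cue,
                            "t_go": t_go,
                            "t_end": t_end,
                        }
                    )
                    trial_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probe placement
# ---------------------------------------------------------------------------

_PROBE_MARGIN = 0.05  # seconds kept clear of interval edges


def place_probes(
    trial_log: pd.DataFrame,
    config: SessionConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Scatter 0-3 (configurable) auditory probes inside each trial.

    Counts are uniform on {probe_min..probe_max}; times are uniform within the
    movement interval (or cue->end when ``allow_planning_probes``) subject to
    ``min_probe_separation``.  Trials too short for the drawn count get a
    reduced count and a log entry.  Returns (probes, reduction_log).
    """
    if seed is None:
        seed = config.seed
    sep = config.min_probe_separation
    rows = []
    reductions: list[str] = []
    scheme_pos = {s: i for i, s in enumerate(config.schemes)}
    for (participant, scheme), trials in trial_log.groupby(["participant", "scheme"], sort=True):
        rng = _rng(seed, _SEED_PROBES, int(participant), scheme_pos[str(scheme)])
        for trial in trials.sort_values("trial_id").itertuples(index=False):
            k = int(rng.integers(config.probe_min, config.probe_max + 1))
            t0 = (trial.t_cue if config.allow_planning_probes else trial.t_go) + _PROBE_MARGIN
            t1 = trial.t_end - _PROBE_MARGIN
            while k > 0 and t1 - t0 < (k - 1) * sep + 1e-9:
                k -= 1
                reductions.append(
                    f"participant={trial.participant} scheme={trial.scheme} "
                    f"trial={trial.trial_id}: interval too short, count reduced to {k}"
                )
            if k <= 0:
                continue
            slack = (t1 - t0) - (k - 1) * sep
            offsets = np.sort(rng.uniform(0.0, slack, size=k))
            times = t0 + offsets + np.arange(k) * sep
            for j, t in enumerate(times):
                rows.append(
                    {
                        "participant": trial.participant,
                        "scheme": trial.scheme,
                        "condition": trial.condition,
                        "trial_id": trial.trial_id,
                        "probe_index": j,
                        "time_s": float(t),
                    }
                )
    probes = pd.DataFrame(
        rows,
        columns=["participant", "scheme", "condition", "trial_id", "probe_index", "time_s"],
    )
    if len(probes):
        probes = probes.sort_values(
            ["participant", "scheme", "time_s"], kind="stable"
        ).reset_index(drop=True)
    return probes, reductions


# ---------------------------------------------------------------------------
# EEG rendering
# ---------------------------------------------------------------------------


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f power spectrum (amplitude ~ f^-1/2)."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(freqs[1:])
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def participant_amp_factors(
    components: Sequence[ComponentSpec],
    noise: NoiseParams,
    seed: int,
    participant: int,
) -> dict[str, float]:
    """Per-participant lognormal amplitude scaling, keyed by component name."""
    out = {}
    for comp in components:
        rng = _rng(seed, _SEED_AMP_FACTOR, participant, _component_code(comp.name))
        sd = noise.participant_amp_sd
        out[comp.name] = float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
    return out


def render_session(
    trial_log: pd.DataFrame,
    probes: pd.DataFrame,
    components: Sequence[ComponentSpec],
    noise: NoiseParams,
    config: SessionConfig,
    participant: int,
    scheme: str,
    seed: int | None = None,
    epoch_length_ms: float = 1100.0,
    noise_stream: int = 0,
) -> tuple[ContinuousRecording, list[EventMarker], dict]:
    """Render one participant x scheme continuous recording.

    ``noise_stream`` selects an independent background/blink noise realization
    while keeping the participant's amplitude factors fixed (used by the
    compact per-cell renderers).

    Returns the recording, its probe event markers, and a ground-truth dict
    with probe times, blink times, injected per-channel amplitudes and any
    probe pairs closer than one epoch length (permitted but flagged).
    """
    if seed is None:
        seed = config.seed
    trials = trial_log[
        (trial_log["participant"] == participant) & (trial_log["scheme"] == scheme)
    ]
    if trials.empty:
        raise ConfigError(f"no trials for participant={participant}, scheme={scheme}")
    sess_probes = probes[
        (probes["participant"] == participant) & (probes["scheme"] == scheme)
    ].sort_values("time_s")

    for comp in components:
        if comp.peak_latency + comp.half_width > epoch_length_ms:
            raise ConfigError(
                f"{comp.name}: template (peak {comp.peak_latency} ms) extends past "
                f"the {epoch_length_ms} ms epoch"
            )

    sfreq = config.sfreq
    tail = 2.0
    n = int(np.ceil((float(trials["t_end"].max()) + tail) * sfreq))
    labels = list(config.channels)
    n_ch = len(labels)
    scheme_pos = {s: i for i, s in enumerate(config.schemes)}[scheme]

    data = np.zeros((n_ch, n))
    noise_rng = _rng(seed, _SEED_NOISE, participant, scheme_pos, noise_stream)
    if noise.pink_rms > 0:
        for c in range(n_ch):
            data[c] += noise.pink_rms * _pink_noise(n, noise_rng)
    if noise.alpha_amplitude > 0:
        phase = noise_rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / sfreq
        alpha = np.sin(2.0 * np.pi * noise.alpha_freq * t + phase)
        for c, label in enumerate(labels):
            w = noise.alpha_weights.get(label, 0.0)
            if w:
                data[c] += noise.alpha_amplitude * w * alpha

    # eyeblinks
    blink_rng = _rng(seed, _SEED_BLINKS, participant, scheme_pos, noise_stream)
    blink_times: list[float] = []
    if noise.blink_rate_per_min > 0:
        duration_s = n / sfreq
        count = blink_rng.poisson(noise.blink_rate_per_min * duration_s / 60.0)
        blink_times = sorted(float(t) for t in blink_rng.uniform(0.0, duration_s, size=count))
        blink_len = int(round(noise.blink_duration * sfreq))
        bump = np.sin(np.pi * np.arange(blink_len) / max(blink_len - 1, 1))
        for bt in blink_times:
            start = int(round(bt * sfreq))
            stop = min(start + blink_len, n)
            for c, label in enumerate(labels):
                w = noise.blink_weights.get(label, 0.0)
                if w:
                    data[c, start:stop] += noise.blink_amplitude * w * bump[: stop - start]

    amp_factors = participant_amp_factors(components, noise, seed, participant)

    # ERP templates at probe times; injected amplitudes recorded per channel
    injected = {
        comp.name: {
            cond: {
                ch: comp.sign * comp.amplitude(scheme, cond) * amp_factors[comp.name]
                * comp.topography.get(ch, 0.0)
                for ch in labels
            }
            for cond in config.conditions
        }
        for comp in components
    }

    events: list[EventMarker] = []
    probe_records = []
    for probe in sess_probes.itertuples(index=False):
        onset = int(round(probe.time_s * sfreq))
        events.append(
            EventMarker(
                sample_index=onset,
                label="probe",
                condition=str(probe.condition),
                scheme=scheme,
                trial_id=int(probe.trial_id),
            )
        )
        probe_records.append(
            {
                "trial_id": int(probe.trial_id),
                "condition": str(probe.condition),
                "time_s": float(probe.time_s),
                "sample_index": onset,
            }
        )
        for comp in components:
            amp = comp.amplitude(scheme, str(probe.condition)) * amp_factors[comp.name]
            if amp == 0.0:
                continue
            support = 2.0 * comp.half_width
            lo_ms = comp.peak_latency - support / 2.0
            hi_ms = comp.peak_latency + support / 2.0
            i0 = max(onset + int(np.floor(lo_ms * sfreq / 1000.0)), 0)
            i1 = min(onset + int(np.ceil(hi_ms * sfreq / 1000.0)) + 1, n)
            if i1 <= i0:
                continue
            times_ms = (np.arange(i0, i1) - onset) * 1000.0 / sfreq
            bump = comp.waveform(times_ms, amp)
            for c, label in enumerate(labels):
                w = comp.topography.get(label, 0.0)
                if w:
                    data[c, i0:i1] += w * bump

    onsets = np.array(sorted(r["sample_index"] for r in probe_records))
    epoch_samples = epoch_length_ms * sfreq / 1000.0
    overlaps = [
        (int(onsets[i]), int(onsets[i + 1]))
        for i in range(len(onsets) - 1)
        if onsets[i + 1] - onsets[i] < epoch_samples
    ]

    recording = ContinuousRecording(labels, sfreq, data)
    ground_truth = {
        "participant": int(participant),
        "scheme": scheme,
        "amp_factors": amp_factors,
        "injected_amplitudes": injected,
        "probes": probe_records,
        "blink_times": blink_times,
        "overlapping_probe_pairs": overlaps,
    }
    return recording, events, ground_truth


# ---------------------------------------------------------------------------
# questionnaires
# ---------------------------------------------------------------------------

_QUESTIONNAIRE_TARGETS = {"DC": (15.1, 3.8), "PRC": (16.3, 4.4)}
REVERSE_SCORED_ITEMS = (1, 3, 7)


def simulate_questionnaires(config: SessionConfig, seed: int | None = None) -> pd.DataFrame:
    """Raw 7-item Likert responses per participant x scheme.

    Items are drawn so that reverse-scored totals land near the reported
    scheme means; items 1, 3, 7 are stored raw (pre-reversal).
    """
    if seed is None:
        seed = config.seed
    rows = []
    for p in range(config.n_participants):
        for s_idx, scheme in enumerate(config.schemes):
            rng = _rng(seed, _SEED_QUESTIONNAIRE, p, s_idx)
            mean, sd = _QUESTIONNAIRE_TARGETS.get(scheme, (16.0, 4.0))
            target = float(np.clip(rng.normal(mean, sd), 7.0, 35.0))
            effective = np.clip(
                np.round(rng.normal(target / 7.0, 0.8, size=7)), 1, 5
            ).astype(int)
            raw = effective.copy()
            for item in REVERSE_SCORED_ITEMS:
                raw[item - 1] = 6 - effective[item - 1]
            row = {"participant": p, "scheme": scheme}
            row.update({f"q{i + 1}": int(raw[i]) for i in range(7)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-level session object
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSession:
    """All generated artifacts except the (lazily rendered) raw EEG."""

    config: SessionConfig
    components: list[ComponentSpec]
    behavior: BehaviorParams
    noise: NoiseParams
    schedules: list[ParticipantSchedule]
    schedule_warnings: list[str]
    trial_log: pd.DataFrame
    probes: pd.DataFrame
    probe_reductions: list[str]
    questionnaires: pd.DataFrame

    def render(
        self, participant: int, scheme: str
    ) -> tuple[ContinuousRecording, list[EventMarker], dict]:
        return render_session(
            self.trial_log,
            self.probes,
            self.components,
            self.noise,
            self.config,
            participant,
            scheme,
            seed=self.config.seed,
        )

    def ground_truth(self) -> dict:
        """Injected quantities for every participant x scheme (no rendering)."""
        out: dict = {"seed": self.config.seed, "participants": {}}
        for sched in self.schedules:
            factors = participant_amp_factors(
                self.components, self.noise, self.config.seed, sched.participant
            )
            injected = {
                scheme: {
                    comp.name: {
                        cond: {
                            ch: comp.sign
                            * comp.amplitude(scheme, cond)
                            * factors[comp.name]
                            * comp.topography.get(ch, 0.0)
                            for ch in self.config.channels
                        }
                        for cond in self.config.conditions
                    }
                    for comp in self.components
                }
                for scheme in self.config.schemes
            }
            probes = self.probes[self.probes["participant"] == sched.participant]
            out["participants"][str(sched.participant)] = {
                "scheme_order": list(sched.scheme_order),
                "condition_order": list(sched.condition_order),
                "amp_factors": factors,
                "injected_amplitudes": injected,
                "n_probes": {
                    scheme: {
                        cond: int(
                            (
                                (probes["scheme"] == scheme) & (probes["condition"] == cond)
                            ).sum()
                        )
                        for cond in self.config.conditions
                    }
                    for scheme in self.config.schemes
                },
            }
        return out


def simulate_session(
    config: SessionConfig,
    components: Sequence[ComponentSpec] | None = None,
    behavior: BehaviorParams | None = None,
    noise: NoiseParams | None = None,
) -> SimulatedSession:
    """Build schedule, behavior, probes, and questionnaires for a cohort."""
    components = list(components) if components is not None else default_components()
    behavior = behavior if behavior is not None else default_behavior()
    noise = noise if noise is not None else NoiseParams()
    schedules, warnings = build_schedule(config)
    trial_log = simulate_behavior(schedules, behavior, config)
    probes, reductions = place_probes(trial_log, config)
    questionnaires = simulate_questionnaires(config)
    return SimulatedSession(
        config=config,
        components=components,
        behavior=behavior,
        noise=noise,
        schedules=schedules,
        schedule_warnings=warnings,
        trial_log=trial_log,
        probes=probes,
        probe_reductions=reductions,
        questionnaires=questionnaires,
    )


# ---------------------------------------------------------------------------
# compact renderers for Monte-Carlo studies
# ---------------------------------------------------------------------------


def render_probe_strip(
    n_probes: int,
    components: Sequence[ComponentSpec],
    noise: NoiseParams,
    scheme: str,
    condition: str,
    seed: int,
    participant: int = 0,
    sfreq: float = 1000.0,
    spacing: float = 1.5,
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz", "VEOG", "HEOG"),
    noise_stream: int = 0,
) -> tuple[ContinuousRecording, list[EventMarker], dict]:
    """Render one cell's worth of probes as a single compact pseudo-trial.

    Used by recovery/power/calibration simulations where rendering full
    sessions (minutes of idle EEG per cell) would dominate the CPU budget.
    Same rendering core as :func:`render_session`: the pseudo-trial is one
    long movement interval whose probes are placed ``spacing`` seconds apart.
    """
    cfg = SessionConfig(
        n_participants=max(participant + 1, 1),
        schemes=("DC", "PRC") if scheme in ("DC", "PRC") else (scheme,),
        conditions=("view", "easy", "hard") if condition in ("view", "easy", "hard") else (condition,),
        probe_min=n_probes,
        probe_max=n_probes,
        min_probe_separation=spacing,
        trial_timeout=max(n_probes * spacing + 2.0, 1.0),
        sfreq=sfreq,
        channels=channels,
        seed=seed,
    )
    duration = n_probes * spacing + 1.0
    trial_log = pd.DataFrame(
        [
            {
                "participant": participant,
                "scheme": scheme,
                "condition": condition,
                "dof": "strip",
                "trial_id": 0,
                "success": True,
                "duration_s": duration,
                "t_cue": 0.2,
                "t_go": 0.4,
                "t_end": 0.4 + duration,
            }
        ]
    )
    probes, _ = place_probes(trial_log, cfg, seed=seed + 7919 * noise_stream)
    return render_session(
        trial_log,
        probes,
        components,
        noise,
        cfg,
        participant,
        scheme,
        seed=seed,
        noise_stream=noise_stream,
    )


def sample_amplitude_cohort(
    n_participants: int,
    components: Sequence[ComponentSpec],
    seed: int,
    schemes: tuple[str, ...] = ("DC", "PRC"),
    conditions: tuple[str, ...] = ("view", "easy", "hard"),
    electrodes: tuple[str, ...] = ("Fz", "Cz", "Pz"),
    between_sd: float = 1.2,
    measurement_sd: float = 0.8,
) -> pd.DataFrame:
    """Draw a measured amplitude table directly from the generative model.

    Analytic shortcut of render->preprocess->score used for large repetition
    counts (type-I calibration): value = injected cell amplitude + Gaussian
    participant effect (``between_sd``) + Gaussian measurement noise
    (``measurement_sd``, the epoch-averaging residual).  Long format matching
    the amplitude table produced by the full pipeline.
    """
    rng = _rng(seed, _SEED_COHORT)
    rows = []
    for p in range(n_participants):
        subject_effect = {c.name: rng.normal(0.0, between_sd) for c in components}
        for scheme in schemes:
            for cond in conditions:
                for comp in components:
                    for ch in electrodes:
                        true = (
                            comp.sign
                            * comp.amplitude(scheme, cond)
                            * comp.topography.get(ch, 0.0)
                        )
                        rows.append(
                            {
                                "participant": p,
                                "scheme": scheme,
                                "condition": cond,
                                "component": comp.name,
                                "electrode": ch,
                                "amplitude_uv": true
                                + subject_effect[comp.name]
                                + rng.normal(0.0, measurement_sd),
                                "n_epochs": 0,
                            }
                        )
    return pd.DataFrame(rows)
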