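"""End-to-end orchestration: simulate -> preprocess -> ERP scoring -> statistics.

``run_all`` is deterministic given the config seed and writes every artifact
(recordings, events, logs, amplitude table, report JSON) under one output
directory.  Stage boundaries match the CLI subcommands so any stage can be
re-run from saved intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import erp as erp_mod
from . import io as io_mod
from . import preprocess as pre_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from .errors import ConfigError

log = logging.getLogger("erpload")

# component -> analysis electrodes for the omnibus ANOVAs
ANALYSIS_SITES: dict[str, tuple[str, ...]] = {
    "N100": ("Cz",),
    "P200": ("Fz", "Cz", "Pz"),
    "P300": ("Pz",),
    "LPP": ("Pz",),
}
ALPHA = 0.05


@dataclass(frozen=True)
class PreprocessParams:
    low: float = 1.0
    high: float = 15.0
    tmin: float = -100.0
    tmax: float = 1000.0
    eog_p2p: float = 100.0
    eeg_abs: float = 75.0
    min_trials: int = 30


@dataclass(frozen=True)
class ErpParams:
    window_mode: str = "fixed"  # "fixed" | "recenter"
    electrodes: tuple[str, ...] = ("Fz", "Cz", "Pz")

    def __post_init__(self) -> None:
        if self.window_mode not in ("fixed", "recenter"):
            raise ConfigError(f"window_mode must be fixed|recenter, got {self.window_mode!r}")


@dataclass(frozen=True)
class OutputParams:
    recording_format: str = "json"  # "json" | "edf" | "csv"
    save_recordings: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    session: sim_mod.SessionConfig = field(default_factory=sim_mod.SessionConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    erp: ErpParams = field(default_factory=ErpParams)
    output: OutputParams = field(default_factory=OutputParams)

    @property
    def seed(self) -> int:
        return self.session.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        def build(klass, section):
            data = dict(raw.get(section, {}))
            try:
                for fld in dataclasses.fields(klass):
                    if fld.name in data and isinstance(data[fld.name], list):
                        data[fld.name] = tuple(data[fld.name])
                return klass(**data)
            except TypeError as exc:
                raise ConfigError(f"bad {section} config: {exc}") from exc

        return cls(
            session=build(sim_mod.SessionConfig, "session"),
            preprocess=build(PreprocessParams, "preprocess"),
            erp=build(ErpParams, "erp"),
            output=build(OutputParams, "output"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def preprocess_recording(
    rec: io_mod.ContinuousRecording,
    events: Sequence[io_mod.EventMarker],
    participant: int,
    params: PreprocessParams,
) -> pre_mod.EpochSet:
    """Filter, epoch, baseline-correct and artifact-flag one recording."""
    filtered = pre_mod.bandpass_filter(rec, params.low, params.high)
    epochs = pre_mod.extract_epochs(filtered, events, participant, params.tmin, params.tmax)
    epochs = pre_mod.baseline_correct(epochs)
    return pre_mod.reject_artifacts(epochs, params.eog_p2p, params.eeg_abs)


def _score_cohort(
    epoch_sets: Mapping[tuple[int, str], pre_mod.EpochSet],
    config: PipelineConfig,
) -> tuple[list, list[pre_mod.InclusionDecision], dict]:
    """Inclusion decisions, amplitude records, and grand averages for a cohort."""
    session = config.session
    cells = [(s, c) for s in session.schemes for c in session.conditions]
    min_trials = config.preprocess.min_trials

    decisions = []
    by_participant: dict[int, dict[tuple[str, str], pre_mod.EpochSet]] = {}
    for (participant, scheme), epochs in epoch_sets.items():
        by_participant.setdefault(participant, {})
    for participant in sorted(by_participant):
        counts: dict[tuple[str, str], int] = {}
        for scheme in session.schemes:
            eps = epoch_sets.get((participant, scheme))
            if eps is None:
                continue
            counts.update(eps.clean_counts())
        decisions.append(
            pre_mod.enforce_min_trials(counts, participant, cells=cells, min_trials=min_trials)
        )

    included = [d.participant for d in decisions if d.included]
    electrodes = tuple(e for e in config.erp.electrodes if e in session.eeg_channels)
    averages: dict[tuple[int, str, str], erp_mod.ErpAverage] = {}
    for participant in included:
        for scheme in session.schemes:
            eps = epoch_sets[(participant, scheme)]
            for condition in session.conditions:
                averages[(participant, scheme, condition)] = erp_mod.average_epochs(
                    eps, participant, scheme, condition, min_trials=min_trials
                )

    grands: dict[str, erp_mod.ErpAverage] = {}
    if len(included) >= 2:
        for condition in session.conditions:
            per_participant = [
                erp_mod.grand_average(
                    [averages[(p, s, condition)] for s in session.schemes]
                )
                if len(session.schemes) > 1
                else averages[(p, session.schemes[0], condition)]
                for p in included
            ]
            grands[condition] = erp_mod.grand_average(per_participant)

    windows = erp_mod.default_windows()
    if config.erp.window_mode == "recenter":
        if len(grands) == 0:
            raise ConfigError("recenter mode needs >= 2 included participants")
        windows = erp_mod.recenter_windows(list(grands.values()), windows)

    records = erp_mod.score_averages(averages.values(), windows, electrodes=electrodes)
    grand_info = {
        "windows": [dataclasses.asdict(w) for w in windows],
        "grand_averages": grands,
    }
    return records, decisions, grand_info


def expected_window_amplitude(
    components: Sequence[sim_mod.ComponentSpec],
    scheme: str,
    condition: str,
    electrode: str,
    window: erp_mod.ComponentWindow,
    params: PreprocessParams | None = None,
    sfreq: float = 1000.0,
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz", "VEOG", "HEOG"),
) -> float:
    """Deterministic noise-free pipeline output for one cell.

    Renders a single probe with no background noise, runs the identical
    preprocessing, and scores the window.  The band-pass is linear, so this
    is the exact expected value of the measured window mean; it differs from
    the raw injected template mean by the (condition-independent,
    amplitude-proportional) filter distortion.
    """
    if params is None:
        params = PreprocessParams()
    rec, events, _ = sim_mod.render_probe_strip(
        1,
        components,
        sim_mod.NoiseParams().silent(),
        scheme,
        condition,
        seed=0,
        sfreq=sfreq,
        spacing=4.0,
        channels=channels,
    )
    eps = preprocess_recording(rec, events, 0, params)
    avg = erp_mod.average_epochs(eps, 0, scheme, condition, min_trials=1)
    return erp_mod.window_mean(avg, window, electrode).amplitude_uv


def analyze(
    amplitudes: pd.DataFrame,
    trial_log: pd.DataFrame | None = None,
    questionnaires: pd.DataFrame | None = None,
) -> dict:
    """The study's statistical endpoints from the long amplitude table.

    Sections: omnibus ANOVA per component x electrode, Tukey-style post-hoc
    workload comparisons, DC-vs-PRC paired contrasts (restricted to
    components with a significant omnibus workload effect), behavior summary
    and contrasts, self-report totals, and the correlation matrix.
    """
    report: dict = {"alpha": ALPHA}
    participants = sorted(amplitudes["participant"].unique())
    n = len(participants)
    report["n_participants"] = n

    omnibus: dict = {}
    workload_significant: list[tuple[str, str]] = []
    for component, sites in ANALYSIS_SITES.items():
        for electrode in sites:
            cell = amplitudes[
                (amplitudes["component"] == component)
                & (amplitudes["electrode"] == electrode)
            ]
            if cell.empty:
                continue
            key = f"{component}@{electrode}"
            entry: dict = {}
            try:
                results = stats_mod.rm_anova(cell)
            except Exception as exc:  # incomplete tables surface as a section note
                omnibus[key] = {"error": str(exc)}
                continue
            for res in results:
                entry[res.effect] = dataclasses.asdict(res)
                entry[res.effect]["significant"] = bool(res.p < ALPHA)
            entry["posthoc_workload"] = [
                dataclasses.asdict(c) for c in stats_mod.posthoc_workload(cell)
            ]
            omnibus[key] = entry
            if entry.get("workload", {}).get("significant"):
                workload_significant.append((component, electrode))
    report["omnibus"] = omnibus
    report["workload_significant"] = [f"{c}@{e}" for c, e in workload_significant]

    # DC vs PRC paired contrasts, restricted to workload-significant peaks
    schemes = sorted(amplitudes["scheme"].unique())
    contrasts: dict = {}
    if len(schemes) == 2:
        a, b = schemes
        for component, electrode in workload_significant:
            for condition in ("easy", "hard"):
                cell = amplitudes[
                    (amplitudes["component"] == component)
                    & (amplitudes["electrode"] == electrode)
                    & (amplitudes["condition"] == condition)
                ]
                if cell.empty:
                    continue
                wide = cell.pivot(index="participant", columns="scheme", values="amplitude_uv")
                if wide.isna().any().any():
                    continue
                res = stats_mod.paired_t(wide[a].to_numpy(), wide[b].to_numpy())
                contrasts[f"{component}@{electrode}:{condition}"] = {
                    **dataclasses.asdict(res),
                    "direction": f"{a} - {b}",
                    "significant": bool(res.p < ALPHA),
                }
    report["scheme_contrasts"] = contrasts

    # behavior
    mean_times: dict[tuple[str, str], pd.Series] = {}
    if trial_log is not None:
        report["behavior"] = behavior_section = {}
        overall = stats_mod.behavior_summary(trial_log)
        behavior_section["summary"] = overall.to_dict(orient="records")
        per_part = (
            trial_log[trial_log["success"].notna()]
            .assign(success=lambda d: d["success"].astype(bool))
            .groupby(["participant", "scheme", "condition"])
            .apply(
                lambda g: pd.Series(
                    {
                        "percent_completed": 100.0 * g["success"].mean(),
                        "mean_time_s": g.loc[g["success"], "duration_s"].mean(),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
        )
        behavior_section["contrasts"] = {}
        if len(schemes) == 2:
            a, b = schemes
            for condition in sorted(per_part["condition"].unique()):
                sub = per_part[per_part["condition"] == condition]
                for measure in ("percent_completed", "mean_time_s"):
                    wide = sub.pivot(index="participant", columns="scheme", values=measure)
                    if wide.isna().any().any() or len(wide) < 2:
                        continue
                    res = stats_mod.paired_t(wide[a].to_numpy(), wide[b].to_numpy())
                    behavior_section["contrasts"][f"{measure}:{condition}"] = {
                        **dataclasses.asdict(res),
                        "direction": f"{a} - {b}",
                        "significant": bool(res.p < ALPHA),
                    }
        for (scheme, condition), grp in per_part.groupby(["scheme", "condition"]):
            mean_times[(scheme, condition)] = grp.set_index("participant")["mean_time_s"]

    # self-report
    totals = None
    if questionnaires is not None:
        totals = stats_mod.score_questionnaire_table(questionnaires)
        section = {"totals": totals.to_dict(orient="records")}
        if len(schemes) == 2:
            wide = totals.pivot(index="participant", columns="scheme", values="total")
            wide = wide.dropna()
            if len(wide) >= 2:
                res = stats_mod.paired_t(
                    wide[schemes[0]].to_numpy(), wide[schemes[1]].to_numpy()
                )
                section["scheme_contrast"] = {
                    **dataclasses.asdict(res),
                    "direction": f"{schemes[0]} - {schemes[1]}",
                    "significant": bool(res.p < ALPHA),
                }
        report["self_report"] = section

    # correlations, per scheme: workload ERPs (hard) x performance x self-report
    correlations: dict = {}
    if trial_log is not None and n >= 3:
        for scheme in schemes:
            variables: dict[str, pd.Series] = {}
            for component, electrode in workload_significant or [
                ("P200", "Cz"),
                ("P300", "Pz"),
                ("LPP", "Pz"),
            ]:
                cell = amplitudes[
                    (amplitudes["component"] == component)
                    & (amplitudes["electrode"] == electrode)
                    & (amplitudes["condition"] == "hard")
                    & (amplitudes["scheme"] == scheme)
                ]
                if not cell.empty:
                    variables[f"{component}@{electrode}:hard"] = cell.set_index(
                        "participant"
                    )["amplitude_uv"]
            if (scheme, "hard") in mean_times:
                variables["mean_time:hard"] = mean_times[(scheme, "hard")]
            if totals is not None:
                variables["self_report"] = totals[totals["scheme"] == scheme].set_index(
                    "participant"
                )["total"]
            names = sorted(variables)
            matrix: dict = {}
            for i, na in enumerate(names):
                for nb in names[i + 1 :]:
                    joined = pd.concat([variables[na], variables[nb]], axis=1).dropna()
                    if len(joined) < 3:
                        continue
                    res = stats_mod.pearson_corr(
                        joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
                    )
                    matrix[f"{na} ~ {nb}"] = dataclasses.asdict(res)
            correlations[scheme] = matrix
    report["correlations"] = correlations
    return report


def run_all(
    config: PipelineConfig,
    out_dir,
    components: Sequence[sim_mod.ComponentSpec] | None = None,
    behavior: sim_mod.BehaviorParams | None = None,
    noise: sim_mod.NoiseParams | None = None,
) -> dict:
    """Execute the full pipeline, writing artifacts under ``out_dir``.

    Returns the report dict (also written to ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session_cfg = config.session
    log.info("simulate: n=%d seed=%d", session_cfg.n_participants, session_cfg.seed)
    sim = sim_mod.simulate_session(session_cfg, components, behavior, noise)

    io_mod.write_trial_log(sim.trial_log, out / "trials.csv")
    io_mod.write_questionnaires(sim.questionnaires, out / "questionnaires.csv")
    _dump_json(sim.ground_truth(), out / "ground_truth.json")
    config.to_yaml(out / "config.yaml")

    epoch_sets: dict[tuple[int, str], pre_mod.EpochSet] = {}
    rejection_rows = []
    fmt = {"json": ".json", "edf": ".edf", "csv": ".csv"}[config.output.recording_format]
    for sched in sim.schedules:
        for scheme in session_cfg.schemes:
            rec, events, _gt = sim.render(sched.participant, scheme)
            stem = f"sub-{sched.participant:02d}_{scheme}"
            if config.output.save_recordings:
                io_mod.write_recording(rec, out / f"{stem}{fmt}")
            io_mod.write_events(events, out / f"{stem}_events.csv", rec.sfreq)
            eps = preprocess_recording(rec, events, sched.participant, config.preprocess)
            epoch_sets[(sched.participant, scheme)] = eps
            rej = pre_mod.rejection_log(eps)
            rejection_rows.append(rej)
            log.info(
                "preprocess: participant=%d scheme=%s events=%d kept=%d flagged=%d dropped=%d",
                sched.participant,
                scheme,
                len(events),
                eps.n_epochs,
                int(eps.artifact_flags.sum()),
                len(eps.dropped),
            )
    pd.concat(rejection_rows, ignore_index=True).to_csv(out / "rejection_log.csv", index=False)

    records, decisions, grand_info = _score_cohort(epoch_sets, config)
    io_mod.write_amplitude_table(records, out / "amplitude_table.csv")
    inclusion = pd.DataFrame(
        [
            {
                "participant": d.participant,
                "included": d.included,
                "min_clean_epochs": min(d.counts.values()),
                "min_trials": d.min_trials,
            }
            for d in decisions
        ]
    )
    inclusion.to_csv(out / "inclusion.csv", index=False)

    # grand-average waveforms for plotting
    waves = []
    for condition, grand in grand_info["grand_averages"].items():
        frame = pd.DataFrame(grand.data.T, columns=grand.channel_labels)
        frame.insert(0, "time_ms", grand.times)
        frame.insert(0, "condition", condition)
        waves.append(frame)
    if waves:
        pd.concat(waves, ignore_index=True).to_csv(
            out / "grand_averages.csv", index=False, float_format="%.17g"
        )

    amplitudes = io_mod.read_amplitude_table(out / "amplitude_table.csv")
    included = set(inclusion[inclusion["included"]]["participant"])
    report: dict = {
        "seed": session_cfg.seed,
        "config": config.to_dict(),
        "inclusion": inclusion.to_dict(orient="records"),
        "n_included": len(included),
        "windows": grand_info["windows"],
        "schedule_warnings": sim.schedule_warnings,
        "probe_count_reductions": len(sim.probe_reductions),
    }
    if len(included) >= 2 and not amplitudes.empty:
        qn = sim.questionnaires[sim.questionnaires["participant"].isin(included)]
        trials = sim.trial_log[sim.trial_log["participant"].isin(included)]
        report["analysis"] = analyze(amplitudes, trials, qn)
    else:
        report["analysis"] = None
        report["analysis_note"] = "fewer than 2 included participants"
    _dump_json(report, out / "report.json")
    return report


def fixture_config(size: str = "tiny", seed: int = 0) -> tuple[
    PipelineConfig, sim_mod.BehaviorParams | None
]:
    """Packaged pipeline configurations for tests and demos.

    ``tiny`` trades realism for speed: 2 participants, 2 channels, 250 Hz,
    short hard trials, probes on every trial, and a lowered inclusion floor
    so the full pipeline runs in seconds.
    """
    if size == "default":
        return PipelineConfig(session=sim_mod.SessionConfig(seed=seed)), None
    if size != "tiny":
        raise ConfigError(f"unknown fixture size {size!r} (tiny|default)")
    session = sim_mod.SessionConfig(
        n_participants=2,
        trials_easy_per_dof=10,
        trials_hard=24,
        trials_view=24,
        probe_min=1,
        probe_max=3,
        min_probe_separation=1.2,
        sfreq=250.0,
        channels=("Pz", "VEOG"),
        seed=seed,
    )
    behavior = sim_mod.BehaviorParams(
        cells={
            ("DC", "easy"): sim_mod.BehaviorCell(0.95, 2.8, 0.8),
            ("PRC", "easy"): sim_mod.BehaviorCell(0.95, 3.0, 0.8),
            ("DC", "hard"): sim_mod.BehaviorCell(0.9, 8.0, 2.0),
            ("PRC", "hard"): sim_mod.BehaviorCell(0.9, 7.0, 2.0),
        }
    )
    config = PipelineConfig(
        session=session,
        preprocess=PreprocessParams(min_trials=20),
        erp=ErpParams(electrodes=("Pz",)),
        output=OutputParams(recording_format="json"),
    )
    return config, behavior


def make_fixtures(size: str, out_dir, seed: int = 0) -> dict:
    """Run the packaged fixture pipeline end-to-end into ``out_dir``."""
    config, behavior = fixture_config(size, seed)
    return run_all(config, out_dir, behavior=behavior)
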