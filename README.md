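# erpload

An end-to-end pipeline for quantifying cognitive workload during
human-machine-interface tasks with the irrelevant auditory probe ERP method:
task-irrelevant novel sounds are presented while participants control a
virtual limb under graded difficulty (passive view / easy / hard) with two
myoelectric control schemes (direct control, DC; pattern recognition
control, PRC), and the amplitude of the probe-evoked ERP components (N100,
P200, P300, LPP) indexes the attentional reserve left over from the primary
task.

Because no raw recordings are distributed with the study, the package ships
a first-class synthetic-session generator with known ground truth:
counterbalanced schedules, per-trial behavior logs, probe event times,
Likert questionnaires, and continuous multi-channel EEG (1/f background,
10 Hz alpha, eyeblink artifacts, raised-cosine component templates whose
amplitudes fall with task difficulty).

## Layout

| module | responsibility |
| --- | --- |
| `erpload.simulate` | seeded session generator + ground truth |
| `erpload.io` | EDF / native container / CSV recordings, events, tables |
| `erpload.preprocess` | 1–15 Hz zero-phase band-pass, −100…1000 ms epochs, baseline correction, threshold artifact rejection, ≥30-clean-epochs inclusion rule |
| `erpload.erp` | cell/grand averages, peak finding, window-mean amplitudes (N100 105–120, P200 190–205, P300 295–330, LPP 570–590 ms) |
| `erpload.stats` | 3×2 repeated-measures ANOVA (+ Greenhouse–Geisser), Tukey-style post-hocs, paired t, Pearson r, behavior and questionnaire scoring |
| `erpload.pipeline` | orchestration, config, report |
| `erpload.cli` | `erpload` command-line interface |

## CLI

```bash
# full pipeline on a synthetic cohort (deterministic given --seed)
erpload run-all --seed 7 --out-dir out/

# tiny packaged fixture (2 participants, 2 channels, seconds to run)
erpload fixtures --size tiny --out-dir out-tiny/

# stage by stage
erpload simulate  --seed 7 --out-dir sim/ --n-participants 18
erpload preprocess --recording sim/sub-00_DC.json --events sim/sub-00_DC_events.csv \
                   --participant 0 --out epochs.npz
erpload erp       --epochs epochs.npz --out amplitudes.csv --electrodes Fz,Cz,Pz
erpload stats     --amplitudes amplitudes.csv --trials sim/trials.csv \
                  --questionnaires sim/questionnaires.csv --out report.json
```

Exit codes: 0 success, 2 configuration error, 3 data validation error.
`run-all` accepts a YAML config (see `config.yaml` written into any output
directory for the full schema); CLI flags override config values.

Window scoring has two modes: the fixed printed windows (default) and
`--recenter`, which re-centers each window on the grand-average peak found
in a component-specific search range while preserving the window width.

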