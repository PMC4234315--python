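import numpy as np
import pandas as pd
import pytest

from erpload import pipeline as pl
from erpload import preprocess as pre
from erpload import erp as erp_mod
from erpload import simulate as sim
from erpload.errors import ConfigError


def small_config(**kw):
    defaults = dict(
        n_participants=2,
        trials_easy_per_dof=2,
        trials_hard=4,
        trials_view=4,
        sfreq=250.0,
        seed=7,
    )
    defaults.update(kw)
    return sim.SessionConfig(**defaults)


class TestBuildSchedule:
    def test_half_of_18_receive_view_first(self):
        schedules, warnings = sim.build_schedule(sim.SessionConfig(n_participants=18))
        view_first = sum(s.condition_order[0] == "view" for s in schedules)
        assert view_first == 9
        assert warnings == []

    def test_smallest_even_case(self):
        schedules, _ = sim.build_schedule(sim.SessionConfig(n_participants=2))
        orders = sorted(s.condition_order[0] for s in schedules)
        assert orders == ["easy", "view"]

    def test_easy_always_precedes_hard(self):
        schedules, _ = sim.build_schedule(sim.SessionConfig(n_participants=18))
        for s in schedules:
            for scheme in s.scheme_order:
                conds = [c for sch, c, _ in s.blocks if sch == scheme]
                assert conds.index("easy") < conds.index("hard")

    def test_scheme_order_split_evenly(self):
        schedules, _ = sim.build_schedule(sim.SessionConfig(n_participants=18))
        dc_first = sum(s.scheme_order[0] == "DC" for s in schedules)
        assert dc_first == 9

    def test_stratified_view_first_within_scheme_order(self):
        schedules, _ = sim.build_schedule(sim.SessionConfig(n_participants=20))
        for first_scheme in ("DC", "PRC"):
            stratum = [s for s in schedules if s.scheme_order[0] == first_scheme]
            vf = sum(s.condition_order[0] == "view" for s in stratum)
            assert vf == len(stratum) // 2

    def test_odd_cohort_warns(self):
        schedules, warnings = sim.build_schedule(sim.SessionConfig(n_participants=3))
        assert len(schedules) == 3
        assert len(warnings) == 1

    def test_trial_counts(self):
        cfg = sim.SessionConfig(n_participants=2)
        schedules, _ = sim.build_schedule(cfg)
        for scheme, condition, trials in schedules[0].blocks:
            if condition == "easy":
                assert len(trials) == 24 * 3
            else:
                assert len(trials) == 32


class TestSimulateBehavior:
    def test_degenerate_noise_hits_mean_exactly(self):
        cfg = small_config()
        schedules, _ = sim.build_schedule(cfg)
        params = sim.BehaviorParams(
            cells={
                (s, c): sim.BehaviorCell(1.0, 3.0, 0.0)
                for s in cfg.schemes
                for c in ("easy", "hard")
            }
        )
        log = sim.simulate_behavior(schedules, params, cfg)
        scored = log[log["success"].notna()]
        assert scored["success"].astype(bool).all()
        assert np.allclose(scored["duration_s"], 3.0)

    def test_dc_hard_mean_within_3_se_of_configured(self):
        # 10,000 draws of the DC-hard cell via a hand-built schedule
        cfg = sim.SessionConfig(n_participants=1, conditions=("hard",), seed=11)
        trials = [{"dof": "3dof"} for _ in range(10_000)]
        sched = sim.ParticipantSchedule(0, ("DC", "PRC"), ("hard",),
                                        [("DC", "hard", trials), ("PRC", "hard", [])])
        params = sim.default_behavior()
        log = sim.simulate_behavior([sched], params, cfg)
        ok = log[(log["scheme"] == "DC") & log["success"].astype(bool)]
        se = 2.18 / np.sqrt(len(ok))
        assert abs(ok["duration_s"].mean() - 15.1) < 3 * se

    def test_zero_success_probability(self):
        cfg = small_config()
        schedules, _ = sim.build_schedule(cfg)
        params = sim.BehaviorParams(
            cells={
                (s, c): sim.BehaviorCell(0.0, 3.0, 1.0)
                for s in cfg.schemes
                for c in ("easy", "hard")
            }
        )
        log = sim.simulate_behavior(schedules, params, cfg)
        scored = log[log["success"].notna()]
        assert not scored["success"].astype(bool).any()
        assert np.allclose(scored["duration_s"], cfg.trial_timeout)

    def test_no_time_exceeds_timeout(self):
        cfg = small_config(n_participants=4)
        schedules, _ = sim.build_schedule(cfg)
        log = sim.simulate_behavior(schedules, sim.default_behavior(), cfg)
        assert (log["duration_s"] <= cfg.trial_timeout).all()

    def test_missing_cell_errors_with_name(self):
        cfg = small_config()
        schedules, _ = sim.build_schedule(cfg)
        params = sim.BehaviorParams(cells={("DC", "easy"): sim.BehaviorCell(1.0, 2.0, 0.1)})
        with pytest.raises(ConfigError, match="hard"):
            sim.simulate_behavior(schedules, params, cfg)

    def test_reproducible_under_seed(self):
        cfg = small_config()
        schedules, _ = sim.build_schedule(cfg)
        a = sim.simulate_behavior(schedules, sim.default_behavior(), cfg)
        b = sim.simulate_behavior(schedules, sim.default_behavior(), cfg)
        pd.testing.assert_frame_equal(a, b)


class TestPlaceProbes:
    def _log(self, cfg):
        schedules, _ = sim.build_schedule(cfg)
        return sim.simulate_behavior(schedules, sim.default_behavior(), cfg)

    def test_no_probes_when_range_is_zero(self):
        cfg = small_config(probe_min=0, probe_max=0)
        probes, _ = sim.place_probes(self._log(cfg), cfg)
        assert probes.empty

    def test_max_count_respected_on_hard_trials(self):
        cfg = sim.SessionConfig(n_participants=2, trials_easy_per_dof=2, seed=3)
        probes, _ = sim.place_probes(self._log(cfg), cfg)
        hard = probes[probes["condition"] == "hard"]
        per_trial = hard.groupby(["participant", "scheme", "trial_id"]).size()
        assert per_trial.max() <= 3

    def test_min_separation_on_1000_trials(self):
        cfg = sim.SessionConfig(
            n_participants=1, conditions=("hard",), trials_hard=1000, seed=5
        )
        trials = [{"dof": "3dof"} for _ in range(1000)]
        sched = sim.ParticipantSchedule(0, ("DC",), ("hard",), [("DC", "hard", trials)])
        log = sim.simulate_behavior([sched], sim.default_behavior(), cfg)
        probes, _ = sim.place_probes(log, cfg)
        gaps = probes.groupby(["participant", "scheme", "trial_id"])["time_s"].apply(
            lambda t: np.diff(np.sort(t)).min() if len(t) > 1 else np.inf
        )
        assert (gaps >= cfg.min_probe_separation - 1e-9).all()

    def test_probes_strictly_inside_movement_interval(self):
        cfg = small_config(n_participants=2)
        log = self._log(cfg)
        probes, _ = sim.place_probes(log, cfg)
        merged = probes.merge(
            log, on=["participant", "scheme", "condition", "trial_id"], suffixes=("", "_t")
        )
        assert (merged["time_s"] > merged["t_go"]).all()
        assert (merged["time_s"] < merged["t_end"]).all()

    def test_short_trials_reduce_count_and_log(self):
        cfg = small_config(probe_min=3, probe_max=3, min_probe_separation=5.0)
        schedules, _ = sim.build_schedule(cfg)
        params = sim.BehaviorParams(
            cells={
                (s, c): sim.BehaviorCell(1.0, 2.0, 0.0)
                for s in cfg.schemes
                for c in ("easy", "hard")
            }
        )
        log = sim.simulate_behavior(schedules, params, cfg)
        probes, reductions = sim.place_probes(log, cfg)
        assert len(reductions) > 0
        per_trial = probes.groupby(["participant", "scheme", "trial_id"]).size()
        assert per_trial.max() <= 1  # 2 s movement cannot hold two probes 5 s apart

    def test_sorted_by_time(self):
        cfg = small_config(n_participants=2)
        probes, _ = sim.place_probes(self._log(cfg), cfg)
        for _, grp in probes.groupby(["participant", "scheme"]):
            assert grp["time_s"].is_monotonic_increasing


class TestRenderEeg:
    def test_noiseless_epoch_equals_template(self):
        comp = sim.default_components()[2]  # P300
        rec, events, gt = sim.render_probe_strip(
            1, [comp], sim.NoiseParams().silent(), "DC", "view", seed=1, spacing=4.0
        )
        eps = pre.extract_epochs(rec, events, 0)
        times = eps.times
        expected = comp.waveform(times, comp.amplitude("DC", "view"))
        pz = eps.channel_labels.index("Pz")
        assert np.max(np.abs(eps.epochs[0, pz] - expected * comp.topography["Pz"])) < 1e-9

    def test_amplitude_recovery_within_3_se_over_100_seeds(self):
        # no band-pass here: the raw pipeline is exactly unbiased for the
        # injected template, so the Monte-Carlo mean must bracket it
        comps = sim.default_components()
        comp = comps[2]
        window = [w for w in erp_mod.default_windows() if w.component == "P300"][0]
        t_grid = np.arange(window.start_ms, window.end_ms + 0.5)
        injected = sum(
            c.waveform(t_grid, c.amplitude("DC", "view")) * c.topography["Pz"] for c in comps
        ).mean()
        noise = sim.NoiseParams(participant_amp_sd=0.0)
        vals = []
        for seed in range(100):
            rec, events, _ = sim.render_probe_strip(40, comps, noise, "DC", "view", seed=seed)
            eps = pre.baseline_correct(pre.extract_epochs(rec, events, 0))
            eps = pre.reject_artifacts(eps)
            avg = erp_mod.average_epochs(eps, 0, "DC", "view", min_trials=10)
            vals.append(erp_mod.window_mean(avg, window, "Pz").amplitude_uv)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - injected) < 3 * se

    def test_condition_ordering_in_95_percent_of_participants(self):
        comps = sim.default_components()
        window = [w for w in erp_mod.default_windows() if w.component == "P300"][0]
        noise = sim.NoiseParams()
        params = pl.PreprocessParams()
        ok = 0
        n = 100
        for p in range(n):
            vals = {}
            for i, cond in enumerate(("view", "easy", "hard")):
                rec, events, _ = sim.render_probe_strip(
                    40, comps, noise, "DC", cond, seed=9000 + p, participant=p,
                    noise_stream=i,
                )
                eps = pl.preprocess_recording(rec, events, p, params)
                avg = erp_mod.average_epochs(eps, p, "DC", cond, min_trials=10)
                vals[cond] = erp_mod.window_mean(avg, window, "Pz").amplitude_uv
            ok += vals["view"] > vals["easy"] > vals["hard"]
        assert ok / n >= 0.95

    def test_seed_determinism(self):
        cfg = small_config()
        sess = sim.simulate_session(cfg)
        rec_a, ev_a, gt_a = sess.render(0, "DC")
        rec_b, ev_b, gt_b = sess.render(0, "DC")
        assert np.array_equal(rec_a.data, rec_b.data)
        assert ev_a == ev_b
        assert gt_a == gt_b

    def test_different_seeds_differ(self):
        a = sim.simulate_session(small_config(seed=1)).render(0, "DC")[0]
        b = sim.simulate_session(small_config(seed=2)).render(0, "DC")[0]
        assert not np.array_equal(a.data, b.data)

    def test_rendering_is_linear_in_components(self):
        comps = sim.default_components()
        first, rest = comps[:1], comps[1:]
        kw = dict(noise=sim.NoiseParams(), scheme="DC", condition="hard", seed=21)
        all_r, _, _ = sim.render_probe_strip(10, comps, kw["noise"], "DC", "hard", seed=21)
        a_r, _, _ = sim.render_probe_strip(10, first, kw["noise"], "DC", "hard", seed=21)
        b_r, _, _ = sim.render_probe_strip(10, rest, kw["noise"], "DC", "hard", seed=21)
        none_r, _, _ = sim.render_probe_strip(10, [], kw["noise"], "DC", "hard", seed=21)
        lhs = a_r.data + b_r.data - none_r.data
        np.testing.assert_allclose(lhs, all_r.data, atol=1e-9)

    def test_probe_free_noiseless_signal_is_zero(self):
        rec, events, _ = sim.render_probe_strip(
            3, sim.default_components(), sim.NoiseParams().silent(), "DC", "easy", seed=2
        )
        onsets = [e.sample_index for e in events]
        mask = np.ones(rec.n_samples, dtype=bool)
        for onset in onsets:
            lo = max(onset - 100, 0)
            hi = min(onset + 1000, rec.n_samples)
            mask[lo:hi] = False
        assert np.max(np.abs(rec.data[:, mask])) < 1e-12

    def test_template_extension_past_epoch_rejected(self):
        comp = sim.ComponentSpec(
            name="late", polarity="positive", peak_latency=1300.0, half_width=50.0,
            topography={"Pz": 1.0}, base_amplitude=5.0,
            attenuation={"view": 1.0, "easy": 1.0, "hard": 1.0},
        )
        with pytest.raises(ConfigError, match="epoch"):
            sim.render_probe_strip(1, [comp], sim.NoiseParams().silent(), "DC", "view", seed=1)

    def test_ground_truth_probe_counts_match_events(self):
        cfg = small_config(probe_min=1)
        sess = sim.simulate_session(cfg)
        gt = sess.ground_truth()
        for sched in sess.schedules:
            for scheme in cfg.schemes:
                _, events, _ = sess.render(sched.participant, scheme)
                counts = gt["participants"][str(sched.participant)]["n_probes"][scheme]
                for cond in cfg.conditions:
                    assert counts[cond] == sum(e.condition == cond for e in events)

    def test_overlapping_probes_flagged(self):
        cfg = small_config(min_probe_separation=0.6, probe_min=2, probe_max=3)
        sess = sim.simulate_session(cfg)
        _, _, gt = sess.render(0, "DC")
        for a, b in gt["overlapping_probe_pairs"]:
            assert (b - a) / cfg.sfreq < 1.1

    def test_blinks_recorded_as_injected(self):
        rec, _, gt = sim.render_probe_strip(
            5, [], sim.NoiseParams(pink_rms=0.0, alpha_amplitude=0.0), "DC", "view", seed=4
        )
        veog = rec.channel_labels.index("VEOG")
        for bt in gt["blink_times"]:
            idx = int(round((bt + 0.2) * 1000))  # mid-blink
            if idx < rec.n_samples:
                assert rec.data[veog, idx] > 50.0


class TestQuestionnaires:
    def test_items_within_likert_range(self):
        q = sim.simulate_questionnaires(sim.SessionConfig(n_participants=18, seed=1))
        items = q[[f"q{i}" for i in range(1, 8)]]
        assert items.min().min() >= 1 and items.max().max() <= 5
        assert len(q) == 36

    def test_deterministic(self):
        cfg = sim.SessionConfig(n_participants=5, seed=9)
        pd.testing.assert_frame_equal(
            sim.simulate_questionnaires(cfg), sim.simulate_questionnaires(cfg)
        )


class TestConfigValidation:
    def test_probe_bounds(self):
        with pytest.raises(ConfigError):
            sim.SessionConfig(probe_min=3, probe_max=1)

    def test_timeout(self):
        with pytest.raises(ConfigError):
            sim.SessionConfig(trial_timeout=0.0)

    def test_empty_conditions(self):
        with pytest.raises(ConfigError):
            sim.SessionConfig(conditions=())

    def test_bad_attenuation(self):
        with pytest.raises(ConfigError):
            sim.ComponentSpec(
                name="x", polarity="positive", peak_latency=100, half_width=10,
                topography={}, base_amplitude=1.0, attenuation={"view": 1.5},
            )
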