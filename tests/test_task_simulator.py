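"""Stop-signal task simulator: sequencing, staircase, race mechanics."""

import itertools

import numpy as np
import pytest

from sst_reliability.task import (
    ConfigurationError,
    RaceModelParams,
    TaskConfig,
    build_trial_sequence,
    read_events,
    simulate_run,
    simulate_session,
    stop_signal_display_duration,
    update_ssd,
    write_events,
)


def stop_gaps(seq):
    """Numbers of go trials before each stop (and the trailing stretch)."""
    gaps, g = [], 0
    for s in seq:
        if s == "stop":
            gaps.append(g)
            g = 0
        else:
            g += 1
    return gaps, g


class TestTrialSequence:
    def test_default_design_counts_and_gaps(self, default_config, rng):
        seq = build_trial_sequence(default_config, rng)
        assert seq.count("go") == 150
        assert seq.count("stop") == 30
        gaps, tail = stop_gaps(seq)
        assert all(3 <= g <= 7 for g in gaps)
        assert tail <= 7

    def test_gap_bounds_over_many_seeds(self, default_config):
        for seed in range(300):
            gaps, tail = stop_gaps(build_trial_sequence(default_config, seed))
            assert all(3 <= g <= 7 for g in gaps)
            assert tail <= 7

    def test_no_stops_degenerates_to_all_go(self):
        cfg = TaskConfig(n_trials_per_run=20, n_stop_per_run=0)
        assert build_trial_sequence(cfg, 0) == ["go"] * 20

    def test_sampled_sequences_lie_in_enumerated_set(self):
        # brute-force oracle: every (g1, g2, g3, tail) composition with
        # gi in [3,7], tail in [0,7] and sum 15 defines a valid sequence
        cfg = TaskConfig(n_trials_per_run=18, n_stop_per_run=3,
                         ssd_initial=50.0)
        valid = set()
        for g in itertools.product(range(3, 8), repeat=3):
            tail = 15 - sum(g)
            if 0 <= tail <= 7:
                seq = []
                for gi in g:
                    seq.extend(["go"] * gi)
                    seq.append("stop")
                seq.extend(["go"] * tail)
                valid.add(tuple(seq))
        sampled = {tuple(build_trial_sequence(cfg, s)) for s in range(200)}
        assert sampled <= valid
        assert len(sampled) > 1  # the sampler actually varies

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigurationError, match="sequencing infeasible"):
            TaskConfig(n_trials_per_run=20, n_stop_per_run=6)  # needs >=18 go


class TestStaircase:
    def test_step_up_after_correct_stop(self, default_config):
        assert update_ssd(500.0, "correct_stop", default_config) == 550.0

    def test_step_down_after_failed_stop_with_floor(self, default_config):
        assert update_ssd(50.0, "incorrect_stop", default_config) == 0.0
        assert update_ssd(0.0, "incorrect_stop", default_config) == 0.0

    def test_ceiling_clamp_strictly_below_900(self, default_config):
        assert update_ssd(850.0, "correct_stop", default_config) == 850.0

    def test_trajectory_never_reaches_900(self, default_config):
        # exhaustive walk: start at 50, always-correct stops climb then pin
        ssd = default_config.ssd_initial
        seen = []
        for _ in range(100):
            seen.append(ssd)
            ssd = update_ssd(ssd, "correct_stop", default_config)
        assert max(seen) == 850.0
        assert all(s < 900.0 for s in seen)

    def test_display_duration_rule(self, default_config):
        assert stop_signal_display_duration(400.0, default_config) == 300.0
        assert stop_signal_display_duration(700.0, default_config) == 300.0
        assert stop_signal_display_duration(750.0, default_config) == 250.0
        with pytest.raises(ValueError):
            stop_signal_display_duration(1000.0, default_config)


class TestSimulateRun:
    def test_counts_and_bounds(self, default_params, default_config):
        log = simulate_run(default_params, default_config, 50.0, 7)
        assert len(log.trials) == 180
        assert log.n_stop_displayed() + log.dropped_stop_signals == 30
        for t in log.trials:
            assert default_config.iti_min <= t.iti <= default_config.iti_max
            if t.trial_type == "stop":
                assert 0.0 <= t.ssd < 900.0
                assert t.outcome in ("correct_stop", "incorrect_stop")
            else:
                assert t.ssd is None

    def test_ssd_bounds_over_many_runs(self, default_params, default_config):
        for seed in range(100):
            log = simulate_run(default_params, default_config, 50.0, seed)
            ssds = [t.ssd for t in log.trials if t.ssd is not None]
            assert min(ssds) >= 0.0 and max(ssds) < 900.0

    def test_stop_never_wins_degenerate_race(self, default_config):
        # stop latency far beyond any go finish: every displayed stop fails
        params = RaceModelParams(ssrt_true=1e9)
        log = simulate_run(params, default_config, 50.0, 3)
        outcomes = {t.outcome for t in log.trials if t.trial_type == "stop"}
        assert outcomes == {"incorrect_stop"}
        # staircase pinned at the floor after the initial descent
        assert log.final_ssd == 0.0

    def test_deterministic_staircase_walk_matches_hand_computation(self):
        # go_sigma = go_tau = 0 makes T_go = 400 exactly; with ssrt = 200
        # the stop wins iff ssd < 200, so from 50 the SSD walks
        # 50,100,150,200 then alternates 150,200,150,...
        cfg = TaskConfig()
        params = RaceModelParams(go_mu=400.0, go_sigma=0.0, go_tau=0.0,
                                 ssrt_true=200.0)
        log = simulate_run(params, cfg, 50.0, 11)
        ssds = [t.ssd for t in log.trials if t.ssd is not None]
        expected = [50.0, 100.0, 150.0, 200.0]
        expected += [150.0, 200.0] * ((len(ssds) - 4) // 2 + 1)
        assert ssds == expected[: len(ssds)]

    def test_same_seed_reproduces_run(self, default_params, default_config):
        a = simulate_run(default_params, default_config, 50.0, 42)
        b = simulate_run(default_params, default_config, 50.0, 42)
        assert a.trials == b.trials

    def test_session_carryover_and_reset(self, default_params):
        cfg = TaskConfig()
        logs = simulate_session(default_params, cfg, seed=5)
        # run 2 starts where run 1 ended
        first_ssd_run2 = next(
            t.ssd for t in logs[1].trials if t.ssd is not None)
        assert abs(first_ssd_run2 - logs[0].final_ssd) < 1e-9
        # a fresh session starts at ssd_initial again
        logs_b = simulate_session(default_params, cfg, seed=5, session=2)
        first_ssd = next(t.ssd for t in logs_b[0].trials if t.ssd is not None)
        assert first_ssd == cfg.ssd_initial

    def test_go_error_taxonomy_probabilities(self, default_config):
        params = RaceModelParams(p_omission=0.2, p_choice_error=0.2, p_late=0.2)
        logs = [simulate_run(params, default_config, 50.0, s) for s in range(30)]
        trials = [t for log in logs for t in log.trials if t.trial_type == "go"]
        frac = {
            o: sum(t.outcome == o for t in trials) / len(trials)
            for o in ("omission", "incorrect_go", "late_go")
        }
        for o in frac:
            assert abs(frac[o] - 0.2) < 0.02
        # rt present iff a response was recorded
        for t in trials:
            assert (t.rt is None) == (t.response == "none")


class TestEventsRoundTrip:
    def test_round_trip_preserves_trials(self, default_params, default_config,
                                         tmp_path):
        log = simulate_run(default_params, default_config, 50.0, 9)
        path = write_events(log, tmp_path / "run1_events.tsv")
        back = read_events(path)
        assert len(back.trials) == len(log.trials) == 180
        for a, b in zip(log.trials, back.trials):
            assert a.trial_type == b.trial_type
            assert a.outcome == b.outcome
            assert a.response == b.response
            if a.rt is None:
                assert b.rt is None
            else:
                assert b.rt == pytest.approx(a.rt, rel=1e-12)
            assert (a.ssd is None) == (b.ssd is None)
            if a.ssd is not None:
                assert b.ssd == a.ssd

    def test_duration_column_is_one_second(self, default_params,
                                           default_config, tmp_path):
        log = simulate_run(default_params, default_config, 50.0, 9)
        path = write_events(log, tmp_path / "ev.tsv")
        lines = path.read_text().strip().splitlines()
        header = lines[0].split("\t")
        i = header.index("duration")
        assert len(lines) - 1 == 180
        assert all(float(line.split("\t")[i]) == 1.0 for line in lines[1:])
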