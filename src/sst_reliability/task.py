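"""Adaptive-staircase stop-signal task simulator.

Generates trial-level stop-signal task (SST) data under an independent
horse-race model: on every trial a "go" process races toward a response, and
on stop trials a "stop" process, launched at the stop-signal delay (SSD),
races to cancel it.  The response is inhibited iff the stop process finishes
first.  The SSD follows a one-up/one-down 50 ms staircase that tracks the
delay at which the subject succeeds on ~50% of stop trials.

Task layout (per run): 180 trials (150 go + 30 stop), 1 s trial duration,
uniform inter-trial interval on [700, 1090] ms, stop trials separated by
3-7 go trials, 2 s lead-in and 5 s tail fixation.  The stop signal is shown
for 300 ms, truncated to (1 s - SSD) when SSD exceeds 700 ms, and the SSD is
clamped to [0, 900) ms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RaceModelParams",
    "TaskConfig",
    "TrialRecord",
    "RunLog",
    "build_trial_sequence",
    "update_ssd",
    "stop_signal_display_duration",
    "simulate_run",
    "simulate_session",
    "write_events",
    "read_events",
]

GO = "go"
STOP = "stop"

GO_OUTCOMES = ("correct_go", "incorrect_go", "omission", "late_go")
STOP_OUTCOMES = ("correct_stop", "incorrect_stop")


class ConfigurationError(ValueError):
    """Raised when a task configuration cannot produce a valid run."""


@dataclass(frozen=True)
class RaceModelParams:
    """Subject-level race-model parameters.

    Go finish times are ex-Gaussian (Gaussian ``go_mu``/``go_sigma`` plus an
    exponential tail with mean ``go_tau``); the stop process has a constant
    latency ``ssrt_true`` so that ground-truth SSRT is known exactly.  The
    error probabilities inject the go-trial error taxonomy (omissions,
    wrong-direction responses, late responses) on top of the race.
    """

    go_mu: float = 400.0
    go_sigma: float = 50.0
    go_tau: float = 60.0
    ssrt_true: float = 200.0
    p_omission: float = 0.0
    p_choice_error: float = 0.0
    p_late: float = 0.0

    def __post_init__(self) -> None:
        for name in ("go_mu", "ssrt_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("go_sigma", "go_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        probs = (self.p_omission, self.p_choice_error, self.p_late)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("error probabilities must lie in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("p_omission + p_choice_error + p_late must be <= 1")


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the in-scanner stop-signal task (all times ms
    unless noted)."""

    n_trials_per_run: int = 180
    n_stop_per_run: int = 30
    ssd_initial: float = 50.0
    ssd_step: float = 50.0
    ssd_max_exclusive: float = 900.0
    ssd_min: float = 0.0
    stop_signal_duration: float = 300.0
    stop_duration_cutoff: float = 700.0
    trial_duration: float = 1000.0
    iti_min: float = 700.0
    iti_max: float = 1090.0
    gap_min: int = 3
    gap_max: int = 7
    run_start_fixation: float = 2.0  # seconds
    run_end_fixation: float = 5.0  # seconds
    n_runs: int = 2
    ssd_carryover_within_session: bool = True

    def __post_init__(self) -> None:
        n_go = self.n_trials_per_run - self.n_stop_per_run
        if n_go < 0:
            raise ConfigurationError("n_stop_per_run exceeds n_trials_per_run")
        if self.n_stop_per_run > 0:
            lo = self.n_stop_per_run * self.gap_min
            hi = self.n_stop_per_run * self.gap_max + self.gap_max
            if not lo <= n_go <= hi:
                raise ConfigurationError(
                    f"sequencing infeasible: need {lo} <= n_go={n_go} <= {hi} "
                    f"for {self.n_stop_per_run} stops with gaps "
                    f"[{self.gap_min}, {self.gap_max}]"
                )
        if not self.ssd_initial < self.ssd_max_exclusive:
            raise ConfigurationError("ssd_initial must be < ssd_max_exclusive")
        if self.iti_min > self.iti_max:
            raise ConfigurationError("iti_min must be <= iti_max")
        if self.gap_min > self.gap_max or self.gap_min < 0:
            raise ConfigurationError("need 0 <= gap_min <= gap_max")


@dataclass
class TrialRecord:
    """One trial of the stop-signal task.

    ``trial_type`` reflects what was actually displayed: a planned stop trial
    on which the subject responded before the stop signal could appear is
    recorded as a go trial (outcome ``correct_go``) and the stop signal moves
    to the following trial.
    """

    trial_index: int
    trial_type: str  # "go" | "stop" (as displayed)
    arrow_direction: str  # "left" | "right"
    ssd: float | None  # ms; present iff a stop signal was displayed
    stop_signal_shown_duration: float | None  # ms
    rt: float | None  # ms; present iff response != "none"
    response: str  # "left" | "right" | "none"
    outcome: str
    iti: float  # ms
    onset: float  # s from run start


@dataclass
class RunLog:
    """All trials of one run plus bookkeeping."""

    subject_id: str
    session: int
    run: int
    trials: list[TrialRecord]
    seed: int | None
    final_ssd: float
    dropped_stop_signals: int = 0  # reclassified stops that fell off the run end
    n_reclassified: int = 0  # stop trials answered before the stop signal

    def outcome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.outcome] = counts.get(t.outcome, 0) + 1
        return counts

    def n_stop_displayed(self) -> int:
        return sum(1 for t in self.trials if t.trial_type == STOP)


def build_trial_sequence(
    config: TaskConfig, rng: np.random.Generator | int | None = None
) -> list[str]:
    """Sample a run's ordered go/stop trial-type sequence.

    Every stop trial is preceded by ``gap_min``..``gap_max`` go trials
    (including the stretch before the first stop); any go trials after the
    last stop number at most ``gap_max``.
    """
    rng = np.random.default_rng(rng)
    n_go = config.n_trials_per_run - config.n_stop_per_run
    if config.n_stop_per_run == 0:
        return [GO] * config.n_trials_per_run

    # Start every pre-stop gap at gap_min, then sprinkle the surplus go
    # trials over the gaps and the tail without exceeding gap_max anywhere.
    gaps = [config.gap_min] * config.n_stop_per_run
    tail = 0
    surplus = n_go - config.n_stop_per_run * config.gap_min
    capacity = [config.gap_max - config.gap_min] * config.n_stop_per_run
    capacity.append(config.gap_max)  # tail slot
    slots = list(range(len(capacity)))
    for _ in range(surplus):
        open_slots = [s for s in slots if capacity[s] > 0]
        s = open_slots[rng.integers(len(open_slots))]
        capacity[s] -= 1
        if s == config.n_stop_per_run:
            tail += 1
        else:
            gaps[s] += 1

    seq: list[str] = []
    for g in gaps:
        seq.extend([GO] * g)
        seq.append(STOP)
    seq.extend([GO] * tail)
    assert len(seq) == config.n_trials_per_run
    return seq


def _balanced_directions(n: int, rng: np.random.Generator) -> list[str]:
    """Left/right labels as balanced as n allows, in random order."""
    half = n // 2
    labels = ["left"] * half + ["right"] * half
    if n % 2:
        labels.append("left" if rng.random() < 0.5 else "right")
    rng.shuffle(labels)
    return labels


def update_ssd(current_ssd: float, stop_outcome: str, config: TaskConfig) -> float:
    """One step of the adaptive staircase.

    A successful stop makes the next stop trial harder (SSD + step, clamped
    strictly below ``ssd_max_exclusive``); a failed stop makes it easier
    (SSD - step, floored at ``ssd_min``).
    """
    if stop_outcome == "correct_stop":
        nxt = current_ssd + config.ssd_step
        return nxt if nxt < config.ssd_max_exclusive else current_ssd
    if stop_outcome == "incorrect_stop":
        return max(current_ssd - config.ssd_step, config.ssd_min)
    raise ValueError(f"not a stop outcome: {stop_outcome!r}")


def stop_signal_display_duration(ssd: float, config: TaskConfig) -> float:
    """Duration the stop signal is shown: 300 ms, shortened to
    (trial duration - SSD) once SSD exceeds 700 ms so it fits in the trial."""
    if ssd < 0 or ssd >= config.trial_duration:
        raise ValueError(f"ssd {ssd} outside [0, {config.trial_duration})")
    if ssd > config.stop_duration_cutoff:
        return config.trial_duration - ssd
    return config.stop_signal_duration


def _draw_go_finish(params: RaceModelParams, rng: np.random.Generator) -> float:
    t = params.go_mu + params.go_sigma * rng.standard_normal()
    if params.go_tau > 0:
        t += rng.exponential(params.go_tau)
    return max(t, 1.0)  # finish times cannot be <= 0


def simulate_run(
    params: RaceModelParams,
    config: TaskConfig,
    starting_ssd: float,
    rng: np.random.Generator | int | None = None,
    *,
    subject_id: str = "sub-01",
    session: int = 1,
    run: int = 1,
    seed: int | None = None,
) -> RunLog:
    """Simulate one run of the stop-signal task.

    Stop-trial mechanics: the go finish time T_go is drawn from the subject's
    ex-Gaussian.  If T_go < SSD the response lands before the stop signal is
    shown -- the trial counts as a correct go and the stop signal swaps onto
    the next trial (dropped and logged if there is none).  Otherwise the stop
    process (launched at SSD, latency ``ssrt_true``) wins iff
    T_go > SSD + ssrt_true (correct stop); a failed stop records rt = T_go.
    The SSD staircase is carried across trials within the run.
    """
    rng = np.random.default_rng(rng if rng is not None else seed)
    seq = build_trial_sequence(config, rng)
    # left/right balanced separately within the planned go and stop trials;
    # directions stay attached to positions if a stop signal is displaced
    go_dirs = iter(_balanced_directions(seq.count(GO), rng))
    stop_dirs = iter(_balanced_directions(seq.count(STOP), rng))
    dirs = [next(stop_dirs) if s == STOP else next(go_dirs) for s in seq]

    ssd = float(starting_ssd)
    onset = float(config.run_start_fixation)
    trials: list[TrialRecord] = []
    dropped = 0
    reclassified = 0
    i = 0
    while i < len(seq):
        is_stop = seq[i] == STOP
        direction = dirs[i]
        iti = float(rng.uniform(config.iti_min, config.iti_max))
        if is_stop:
            t_go = _draw_go_finish(params, rng)
            if t_go < ssd:
                # Response before the stop signal: correct go; the stop
                # signal moves onto the next trial (swap keeps counts fixed).
                reclassified += 1
                nxt = i + 1
                if nxt < len(seq):
                    seq[i], seq[nxt] = seq[nxt], seq[i]
                else:
                    dropped += 1
                trials.append(
                    TrialRecord(i, GO, direction, None, None, t_go, direction,
                                "correct_go", iti, onset)
                )
            else:
                shown = stop_signal_display_duration(ssd, config)
                if t_go > ssd + params.ssrt_true:
                    trials.append(
                        TrialRecord(i, STOP, direction, ssd, shown, None,
                                    "none", "correct_stop", iti, onset)
                    )
                    ssd = update_ssd(ssd, "correct_stop", config)
                else:
                    trials.append(
                        TrialRecord(i, STOP, direction, ssd, shown, t_go,
                                    direction, "incorrect_stop", iti, onset)
                    )
                    ssd = update_ssd(ssd, "incorrect_stop", config)
        else:
            t_go = _draw_go_finish(params, rng)
            u = rng.random()
            if u < params.p_omission:
                trials.append(
                    TrialRecord(i, GO, direction, None, None, None, "none",
                                "omission", iti, onset)
                )
            elif u < params.p_omission + params.p_choice_error:
                wrong = "right" if direction == "left" else "left"
                trials.append(
                    TrialRecord(i, GO, direction, None, None, t_go, wrong,
                                "incorrect_go", iti, onset)
                )
            elif u < params.p_omission + params.p_choice_error + params.p_late:
                rt = config.trial_duration + rng.uniform(0.0, iti)
                trials.append(
                    TrialRecord(i, GO, direction, None, None, rt, direction,
                                "late_go", iti, onset)
                )
            else:
                if t_go > config.trial_duration + iti:
                    trials.append(
                        TrialRecord(i, GO, direction, None, None, None,
                                    "none", "omission", iti, onset)
                    )
                elif t_go > config.trial_duration:
                    trials.append(
                        TrialRecord(i, GO, direction, None, None, t_go,
                                    direction, "late_go", iti, onset)
                    )
                else:
                    trials.append(
                        TrialRecord(i, GO, direction, None, None, t_go,
                                    direction, "correct_go", iti, onset)
                    )
        onset += (config.trial_duration + iti) / 1000.0
        i += 1

    return RunLog(subject_id, session, run, trials, seed, ssd, dropped,
                  reclassified)


def simulate_session(
    params: RaceModelParams,
    config: TaskConfig,
    seed: int,
    *,
    subject_id: str = "sub-01",
    session: int = 1,
) -> list[RunLog]:
    """Simulate all runs of one task administration.

    The SSD starts at ``ssd_initial`` at the beginning of the session and
    (by default) carries over from run to run within the session; each new
    session resets it.
    """
    rng = np.random.default_rng(seed)
    ssd = config.ssd_initial
    logs: list[RunLog] = []
    for r in range(1, config.n_runs + 1):
        log = simulate_run(
            params, config, ssd, rng,
            subject_id=subject_id, session=session, run=r, seed=seed,
        )
        logs.append(log)
        if config.ssd_carryover_within_session:
            ssd = log.final_ssd
        else:
            ssd = config.ssd_initial
    return logs


_EVENT_COLUMNS = [
    "onset", "duration", "trial_index", "trial_type", "arrow_direction",
    "response", "response_time", "ssd", "stop_signal_duration", "outcome",
    "iti",
]


def _fmt(v: float | None, scale: float = 1.0) -> str:
    if v is None:
        return "n/a"
    return repr(v * scale)


def write_events(
    run_log: RunLog, path: str | Path, *, trial_duration_ms: float = 1000.0
) -> Path:
    """Write a run as a BIDS-style events TSV (onset/duration in seconds,
    response_time in seconds, ssd in ms).  ``duration`` is the arrow-event
    (regressor) duration, the full trial duration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dur = trial_duration_ms / 1000.0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_EVENT_COLUMNS)
        for t in run_log.trials:
            w.writerow([
                repr(t.onset),
                repr(dur),
                t.trial_index,
                t.trial_type,
                t.arrow_direction,
                t.response,
                _fmt(t.rt, 1e-3),
                _fmt(t.ssd),
                _fmt(t.stop_signal_shown_duration),
                t.outcome,
                repr(t.iti),
            ])
    return path


def read_events(
    path: str | Path,
    *,
    subject_id: str = "sub-01",
    session: int = 1,
    run: int = 1,
) -> RunLog:
    """Read an events TSV written by :func:`write_events` back into a RunLog.

    ``final_ssd``/``dropped_stop_signals`` are not stored in the events file
    and come back as the last displayed SSD / 0.
    """
    path = Path(path)
    trials: list[TrialRecord] = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            rt = None if row["response_time"] == "n/a" else float(row["response_time"]) * 1e3
            ssd = None if row["ssd"] == "n/a" else float(row["ssd"])
            shown = (
                None
                if row["stop_signal_duration"] == "n/a"
                else float(row["stop_signal_duration"])
            )
            trials.append(
                TrialRecord(
                    int(row["trial_index"]), row["trial_type"],
                    row["arrow_direction"], ssd, shown, rt, row["response"],
                    row["outcome"], float(row["iti"]), float(row["onset"]),
                )
            )
    final_ssd = next((t.ssd for t in reversed(trials) if t.ssd is not None), float("nan"))
    return RunLog(subject_id, session, run, trials, None, final_ssd)
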