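#!/usr/bin/env python
"""Simulate the behavioral cohort and summarize task performance.

56 subjects complete two runs of the adaptive stop-signal task at Time1;
44 of them return for Time2.  Writes per-session behavioral summaries, the
paired Time1/Time2 comparison table, and one example subject's BIDS-style
events files under results/behavior/.
"""

import sys
from pathlib import Path

import numpy as np

from sst_reliability.behavior import (
    compare_sessions,
    summaries_to_frame,
    summarize_subject,
)
from sst_reliability.task import RaceModelParams, TaskConfig, simulate_session, write_events

OUT = Path(__file__).resolve().parent.parent / "results" / "behavior"
SEED = 20260901
N_SUBJECTS, N_RETURN = 56, 44


def main() -> None:
    cfg = TaskConfig()
    # population: subject-level parameters drawn around realistic values
    rng = np.random.default_rng(SEED)
    frames = {}
    for ses in (1, 2):
        rows = []
        n = N_SUBJECTS if ses == 1 else N_RETURN
        for i in range(n):
            params = RaceModelParams(
                go_mu=float(rng.normal(420.0, 40.0)),
                go_sigma=float(rng.uniform(35.0, 65.0)),
                go_tau=float(rng.uniform(40.0, 80.0)),
                ssrt_true=float(rng.normal(220.0, 30.0)),
                p_omission=0.007, p_choice_error=0.015, p_late=0.017,
            )
            logs = simulate_session(params, cfg, seed=SEED + 100 * i + ses,
                                    subject_id=f"S{i + 1:03d}", session=ses)
            rows.append(summarize_subject(logs))
            if i == 0 and ses == 1:
                for log in logs:
                    write_events(log, OUT / "events" /
                                 f"sub-S001_ses-1_run-{log.run}_events.tsv")
        frames[ses] = summaries_to_frame(rows)
        frames[ses].to_csv(OUT / f"behavior_time{ses}.csv", index=False)

    table = compare_sessions(frames[1], frames[2])
    table.to_csv(OUT / "session_comparison.csv", index=False)

    pct1 = frames[1]["pct_correct_stop"]
    pct2 = frames[2]["pct_correct_stop"]
    print(f"Time1: {len(frames[1])} subjects, "
          f"{pct1.mean():.2f}% ({pct1.std(ddof=1):.2f}) correct stops")
    print(f"Time2: {len(frames[2])} subjects, "
          f"{pct2.mean():.2f}% ({pct2.std(ddof=1):.2f}) correct stops")
    print("The adaptive staircase held stop accuracy near 50% in both "
          "sessions; no behavioral variable shifted significantly between "
          "sessions:" if (table['p'] > 0.05).all() else "Session shifts:")
    print(table[["variable", "time1_mean", "time2_mean", "p"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
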