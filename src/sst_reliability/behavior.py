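"""Behavioral outcome variables of the stop-signal task.

Per subject and session (both runs pooled): counts of correct go/stop
trials, mean go and failed-stop reaction times, mean stop-signal delay,
percent successful stops, and the stop-signal reaction time (SSRT).

SSRT estimators
---------------
Under the race model the stopping latency is not observed directly.  With
p = P(respond | stop signal) and the pooled go-RT distribution G:

* integration method (default): SSRT = G^{-1}(p) - mean SSD, using the
  ceil(p*N)-th order statistic of the N pooled go RTs as the quantile;
* mean method: SSRT = mean(go RT) - mean SSD.

Both degenerate when p is 0 or 1 (all stops succeeded or failed); the
summary then carries a missing SSRT with a reason code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import RunLog

__all__ = [
    "BehavioralSummary",
    "compute_ssrt",
    "summarize_subject",
    "summaries_to_frame",
    "compare_sessions",
]

#: go outcomes that contribute an RT to the SSRT go-RT pool
_RESPONDED_GO = ("correct_go", "incorrect_go", "late_go")


@dataclass
class BehavioralSummary:
    """Table-1-style behavioral summary for one subject at one session."""

    subject_id: str
    session: int
    n_correct_go: int
    n_correct_stop: int
    n_incorrect_stop: int
    n_other_errors: int
    n_stop_displayed: int
    correct_go_mean_rt: float  # ms (nan if no correct go trials)
    incorrect_stop_mean_rt: float  # ms
    mean_ssd: float  # ms
    ssrt: float  # ms (nan when undefined)
    ssrt_missing_reason: str | None
    pct_correct_stop: float  # %


def compute_ssrt(
    go_rts: Sequence[float],
    p_respond_given_signal: float,
    mean_ssd: float,
    method: str = "integration",
) -> tuple[float, str | None]:
    """Estimate SSRT; returns (value_ms, missing_reason).

    ``go_rts`` is the pool of go trials with a recorded response.  The
    integration quantile is the ceil(p*N)-th order statistic, a rank-based
    convention that is reproducible across platforms.
    """
    rts = np.sort(np.asarray(list(go_rts), dtype=float))
    if rts.size == 0:
        return float("nan"), "no responded go trials"
    p = float(p_respond_given_signal)
    if method == "mean":
        return float(rts.mean() - mean_ssd), None
    if method != "integration":
        raise ValueError(f"unknown SSRT method: {method!r}")
    if not 0.0 < p < 1.0:
        return float("nan"), f"p_respond={p:g} outside (0, 1)"
    k = math.ceil(p * rts.size)
    return float(rts[k - 1] - mean_ssd), None


def summarize_subject(
    run_logs: Iterable[RunLog], method: str = "integration"
) -> BehavioralSummary:
    """Pool a session's runs and compute the behavioral summary."""
    logs = list(run_logs)
    if not logs:
        raise ValueError("at least one run required")
    subject_id = logs[0].subject_id
    session = logs[0].session
    trials = [t for log in logs for t in log.trials]

    by_outcome: dict[str, list] = {}
    for t in trials:
        by_outcome.setdefault(t.outcome, []).append(t)

    n_cgo = len(by_outcome.get("correct_go", []))
    n_cstop = len(by_outcome.get("correct_stop", []))
    n_istop = len(by_outcome.get("incorrect_stop", []))
    n_other = sum(
        len(by_outcome.get(o, [])) for o in ("incorrect_go", "omission", "late_go")
    )
    n_stop_disp = n_cstop + n_istop

    cgo_rts = [t.rt for t in by_outcome.get("correct_go", []) if t.rt is not None]
    istop_rts = [t.rt for t in by_outcome.get("incorrect_stop", []) if t.rt is not None]
    ssds = [t.ssd for t in trials if t.ssd is not None]

    mean_ssd = float(np.mean(ssds)) if ssds else float("nan")
    pct = 100.0 * n_cstop / n_stop_disp if n_stop_disp else float("nan")
    p_respond = n_istop / n_stop_disp if n_stop_disp else float("nan")

    go_pool = [
        t.rt
        for t in trials
        if t.outcome in _RESPONDED_GO and t.rt is not None
    ]
    if go_pool and n_stop_disp:
        ssrt, reason = compute_ssrt(go_pool, p_respond, mean_ssd, method)
    else:
        ssrt, reason = float("nan"), "no go RTs or no displayed stop trials"

    return BehavioralSummary(
        subject_id=subject_id,
        session=session,
        n_correct_go=n_cgo,
        n_correct_stop=n_cstop,
        n_incorrect_stop=n_istop,
        n_other_errors=n_other,
        n_stop_displayed=n_stop_disp,
        correct_go_mean_rt=float(np.mean(cgo_rts)) if cgo_rts else float("nan"),
        incorrect_stop_mean_rt=float(np.mean(istop_rts)) if istop_rts else float("nan"),
        mean_ssd=mean_ssd,
        ssrt=ssrt,
        ssrt_missing_reason=reason,
        pct_correct_stop=pct,
    )


#: behavioral variables reported in the session-comparison table
VARIABLES = [
    "n_correct_go",
    "n_correct_stop",
    "correct_go_mean_rt",
    "incorrect_stop_mean_rt",
    "mean_ssd",
    "ssrt",
    "pct_correct_stop",
]


def summaries_to_frame(summaries: Iterable[BehavioralSummary]) -> pd.DataFrame:
    """Stack summaries into a subject x variable frame (one row per
    subject/session)."""
    rows = []
    for s in summaries:
        rows.append(
            {"subject_id": s.subject_id, "session": s.session,
             **{v: getattr(s, v) for v in VARIABLES}}
        )
    return pd.DataFrame(rows)


def compare_sessions(
    frame_t1: pd.DataFrame,
    frame_t2: pd.DataFrame,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable session means/SDs and two-sided paired t-tests.

    Inputs are frames indexed (or keyed) by ``subject_id`` with one column
    per variable; only subjects present at both sessions enter each test,
    and pairs with a missing value for a variable are dropped for that
    variable.  Variables with fewer than 3 complete pairs are skipped.
    """
    t1 = frame_t1.set_index("subject_id") if "subject_id" in frame_t1 else frame_t1
    t2 = frame_t2.set_index("subject_id") if "subject_id" in frame_t2 else frame_t2
    shared = t1.index.intersection(t2.index)
    variables = list(variables) if variables is not None else [
        v for v in VARIABLES if v in t1.columns and v in t2.columns
    ]
    rows = []
    for v in variables:
        a = t1.loc[shared, v].astype(float)
        b = t2.loc[shared, v].astype(float)
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        if n < 3:
            rows.append({"variable": v, "n": n, "t": np.nan, "p": np.nan,
                         "time1_mean": np.nan, "time1_sd": np.nan,
                         "time2_mean": np.nan, "time2_sd": np.nan,
                         "note": "skipped: <3 complete pairs"})
            continue
        av, bv = a[ok].to_numpy(), b[ok].to_numpy()
        diff = av - bv
        note = ""
        if np.all(diff == 0):
            t_stat, p = 0.0, 1.0
        elif diff.std(ddof=1) == 0:
            # constant non-zero shift: the paired t diverges
            t_stat = math.copysign(math.inf, diff.mean())
            p = 0.0
            note = "degenerate: zero within-pair variance, p reported as 0"
        else:
            t_stat, p = stats.ttest_rel(av, bv)
        rows.append({
            "variable": v, "n": n,
            "time1_mean": av.mean(), "time1_sd": av.std(ddof=1),
            "time2_mean": bv.mean(), "time2_sd": bv.std(ddof=1),
            "t": float(t_stat), "p": float(p), "note": note,
        })
    return pd.DataFrame(rows)
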