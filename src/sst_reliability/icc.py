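"""Consistency intraclass correlations: ICC(C,1) / ICC(3,1).

Reliability of test-retest (Time1 vs Time2), within-session (run 1 vs
run 2) and twin-pair (twin 1 vs twin 2) measurements is quantified with the
single-measure consistency ICC from a two-way mixed model (rows = subjects
or pairs, columns = the k repeated measurements), estimated by method of
moments:

    ICC(C,1) = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

where MS_rows is the between-rows mean square and MS_error the residual
mean square of the row x column ANOVA.  Negative values are retained: they
are informative about the distribution of reliabilities.  For k = 2 the
estimator reduces to 2*cov(x1, x2) / (var(x1) + var(x2)), which the
vectorised per-parcel routines use.

ICCs are banded poor (< 0.4), fair ([0.4, 0.6)), good ([0.6, 0.75)) and
excellent ([0.75, 1]); the half-open intervals close the gaps left by the
conventional verbal definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICCResult",
    "icc_consistency",
    "icc_columns",
    "twin_icc",
    "classify_icc",
    "fisher_z",
    "fisher_z_inverse",
    "batch_icc",
]


@dataclass
class ICCResult:
    target: str | None
    icc: float  # nan when undefined
    n_complete: int
    ms_rows: float
    ms_error: float
    category: str  # poor | fair | good | excellent | undefined
    reason: str | None = None


def classify_icc(icc: float) -> str:
    """Cicchetti-style verbal band for an ICC in [-1, 1]."""
    if not np.isfinite(icc):
        return "undefined"
    if not -1.0 <= icc <= 1.0:
        raise ValueError(f"icc {icc} outside [-1, 1]")
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def icc_consistency(
    data: np.ndarray | pd.DataFrame, *, target: str | None = None, min_n: int = 3
) -> ICCResult:
    """Two-way mixed, single-measure consistency ICC on an n x k matrix.

    Rows with any missing value are dropped (complete-case); the mean
    squares come from the standard two-way ANOVA decomposition.  Undefined
    results (too few complete rows, or a zero denominator) are flagged
    rather than coerced.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("data must be n x k with k >= 2")
    complete = ~np.isnan(x).any(axis=1)
    x = x[complete]
    n, k = x.shape
    if n < min_n:
        return ICCResult(target, float("nan"), n, float("nan"), float("nan"),
                         "undefined", f"only {n} complete rows (< {min_n})")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))

    denom = ms_rows + (k - 1) * ms_error
    if denom <= 0:
        return ICCResult(target, float("nan"), n, ms_rows, ms_error,
                         "undefined", "zero denominator (no variance)")
    icc = (ms_rows - ms_error) / denom
    return ICCResult(target, float(icc), n, float(ms_rows), float(ms_error),
                     classify_icc(icc))


def twin_icc(
    pairs: np.ndarray | pd.DataFrame, *, target: str | None = None
) -> ICCResult:
    """Intrapair (familiality) ICC: rows = twin pairs, columns =
    (twin 1, twin 2); identical estimator as test-retest consistency."""
    return icc_consistency(pairs, target=target)


def icc_columns(x1: np.ndarray, x2: np.ndarray, min_n: int = 3) -> np.ndarray:
    """Vectorised per-column k=2 consistency ICC with complete-case
    filtering per column.

    ``x1``/``x2`` are n x p (subjects x targets) with NaN for missing.
    Returns a length-p array; NaN where fewer than ``min_n`` complete pairs
    or zero denominator.  Identical to :func:`icc_consistency` column by
    column (for k = 2 the ANOVA form reduces to 2*Sxy / (Sxx + Syy)).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have the same shape")
    m = ~np.isnan(x1) & ~np.isnan(x2)
    n = m.sum(axis=0)
    a = np.where(m, x1, 0.0)
    b = np.where(m, x2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = a.sum(axis=0) / n
        mb = b.sum(axis=0) / n
        sxx = (a * a).sum(axis=0) - n * ma * ma
        syy = (b * b).sum(axis=0) - n * mb * mb
        sxy = (a * b).sum(axis=0) - n * ma * mb
        icc = 2.0 * sxy / (sxx + syy)
    icc = np.where((n >= min_n) & ((sxx + syy) > 0), icc, np.nan)
    return icc


def fisher_z(r: float | np.ndarray, clip: float = 0.999999) -> float | np.ndarray:
    """Fisher r-to-z (atanh); |r| >= 1 is clipped to +/-``clip`` so that
    degenerate ICCs of exactly 1 remain comparable."""
    r = np.clip(r, -clip, clip)
    out = np.arctanh(r)
    return float(out) if np.isscalar(r) or np.ndim(out) == 0 else out

def fisher_z_inverse(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(z)
    return float(out) if np.ndim(out) == 0 else out


def batch_icc(
    panels,
    design: str,
    *,
    contrast: str,
    run: int | None = None,
    session: int | None = None,
) -> pd.DataFrame:
    """Per-parcel ICCs for one reliability design.

    ``panels`` is a :class:`~sst_reliability.synth.PanelSet` (or any object
    with ``get(contrast, session, run)`` and ``session_mean(contrast,
    session)`` returning subjects x parcels frames).

    Designs
    -------
    between_session_full : run-averaged betas, Time1 vs Time2
    between_session_run  : run ``run`` only, Time1 vs Time2
    within_session       : session ``session``, run 1 vs run 2
    """
    if design == "between_session_full":
        a = panels.session_mean(contrast, 1)
        b = panels.session_mean(contrast, 2)
    elif design == "between_session_run":
        if run is None:
            raise ValueError("between_session_run requires run=")
        a = panels.get(contrast, 1, run)
        b = panels.get(contrast, 2, run)
    elif design == "within_session":
        if session is None:
            raise ValueError("within_session requires session=")
        a = panels.get(contrast, session, 1)
        b = panels.get(contrast, session, 2)
    else:
        raise ValueError(f"unknown design: {design!r}")
    if a is None or b is None:
        raise ValueError(
            f"design {design!r} needs session/run cells missing from the panel "
            f"(contrast={contrast!r}, session={session}, run={run})"
        )

    a, b = a.align(b, join="inner", axis=0)
    icc = icc_columns(a.to_numpy(), b.to_numpy())
    n = (~np.isnan(a.to_numpy()) & ~np.isnan(b.to_numpy())).sum(axis=0)
    return pd.DataFrame({
        "parcel_id": a.columns,
        "design": design,
        "icc": icc,
        "n": n,
        "category": [classify_icc(v) if np.isfinite(v) else "undefined" for v in icc],
    })
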