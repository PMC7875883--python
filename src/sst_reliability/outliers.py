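"""Iterative z-score outlier exclusion and pairwise missingness propagation.

Each variable (behavioral measure, parcel beta, motion scalar) is screened
separately within each timepoint sample: values are standardized to zero
mean / unit SD over the non-missing entries and |z| > 3 is recoded as
missing.  Because removal changes the shape of the distribution, the
procedure is reiterated a fixed 10 times (new outliers may emerge as the SD
shrinks).  Afterwards, the matched value at the other timepoint -- and, for
twin analyses, in the co-twin -- is also set missing so that reliability and
familiality use the same complete pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OutlierReport",
    "iterative_z_exclusion",
    "exclude_outliers_frame",
    "propagate_missing_timepoints",
    "propagate_missing_twins",
]


@dataclass
class OutlierReport:
    variable: str
    n_input: int  # non-missing values before exclusion
    per_iteration: list[int] = field(default_factory=list)

    @property
    def total_excluded(self) -> int:
        return sum(self.per_iteration)

    @property
    def percent_excluded(self) -> float:
        return 100.0 * self.total_excluded / self.n_input if self.n_input else 0.0


def iterative_z_exclusion(
    x, z_cut: float = 3.0, n_iter: int = 10, *, variable: str = "x"
) -> tuple[np.ndarray, OutlierReport]:
    """Recode |z| > ``z_cut`` values as missing, reiterated ``n_iter`` times.

    The SD (ddof=1) is recomputed from the surviving values at every
    iteration; an iteration with zero SD excludes nothing.  Always runs the
    full ``n_iter`` iterations (a fixed count, not convergence).  Returns
    the vector with exclusions as NaN plus a per-iteration report.
    """
    out = np.asarray(x, dtype=float).copy()
    report = OutlierReport(variable, int(np.sum(~np.isnan(out))))
    if report.n_input < 3:
        raise ValueError("need at least 3 non-missing values")
    for _ in range(n_iter):
        vals = out[~np.isnan(out)]
        sd = vals.std(ddof=1) if vals.size >= 2 else 0.0
        if sd == 0 or not np.isfinite(sd):
            report.per_iteration.append(0)
            continue
        z = (out - vals.mean()) / sd
        bad = np.abs(z) > z_cut  # NaNs compare False
        report.per_iteration.append(int(np.nansum(bad)))
        out[bad] = np.nan
    return out, report


def exclude_outliers_frame(
    df: pd.DataFrame, z_cut: float = 3.0, n_iter: int = 10
) -> tuple[pd.DataFrame, list[OutlierReport]]:
    """Column-wise iterative exclusion over a subjects x variables frame."""
    out = df.copy().astype(float)
    reports = []
    for col in out.columns:
        cleaned, rep = iterative_z_exclusion(
            out[col].to_numpy(), z_cut, n_iter, variable=str(col)
        )
        out[col] = cleaned
        reports.append(rep)
    return out, reports


def propagate_missing_timepoints(
    t1: pd.DataFrame, t2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A value missing at one session forces the matched subject/variable
    missing at the other session.  Subjects absent from one frame entirely
    (e.g. Time2 non-returners) keep their data at the other session only if
    present in both frames; alignment is by index/columns intersection for
    the propagation, other cells are left untouched."""
    a = t1.copy()
    b = t2.copy()
    shared_rows = a.index.intersection(b.index)
    shared_cols = a.columns.intersection(b.columns)
    mask = a.loc[shared_rows, shared_cols].isna() | b.loc[shared_rows, shared_cols].isna()
    a.loc[shared_rows, shared_cols] = a.loc[shared_rows, shared_cols].mask(mask)
    b.loc[shared_rows, shared_cols] = b.loc[shared_rows, shared_cols].mask(mask)
    return a, b


def propagate_missing_twins(df: pd.DataFrame, registry) -> pd.DataFrame:
    """A value missing in one twin forces the same variable missing in the
    co-twin.  ``registry`` is a TwinRegistry; every subject in ``df`` must
    belong to a pair."""
    pair_of = registry.pair_of()
    unpaired = [s for s in df.index if s not in pair_of]
    if unpaired:
        raise ValueError(f"subjects not in twin registry: {unpaired}")
    out = df.copy()
    for _, row in registry.table.iterrows():
        a, b = str(row["twin1"]), str(row["twin2"])
        if a not in out.index or b not in out.index:
            continue
        mask = out.loc[a].isna() | out.loc[b].isna()
        out.loc[a, mask] = np.nan
        out.loc[b, mask] = np.nan
    return out
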