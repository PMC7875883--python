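"""Factors potentially affecting test-retest reliability.

Cross-parcel analyses relating TRR to effect size (Cohen's d), activation
magnitude, familiality, session/run design, and head motion:

* a per-parcel factor table (ICC, Cohen's d, mean/SD of Time1 run-averaged
  betas, familiality, cortical/subcortical stratum) and its pairwise
  Pearson correlation matrix, stratified by cortex vs subcortex;
* paired comparisons of ICC sets (within- vs between-session, single-run
  vs combined-run) as paired t-tests on Fisher r-to-z transformed ICCs;
* the per-subject motion/stability analysis: mean |Time1 - Time2| beta
  difference over all parcels against the subject's average motion.

Cross-parcel p-values treat parcels as independent units (descriptive, as
spatial dependence is ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .icc import fisher_z

__all__ = [
    "build_factor_table",
    "factor_correlations",
    "compare_icc_sets",
    "motion_stability",
]


def build_factor_table(
    panels,
    icc_table: pd.DataFrame,
    familiality_table: pd.DataFrame | None,
    *,
    contrast: str,
) -> pd.DataFrame:
    """One row per parcel: TRR ICC, Cohen's d and moments of Time1
    run-averaged betas, familiality ICC, and the cortical flag.

    Cohen's d is the one-sample effect size of Time1 run-averaged betas
    against zero: across-subject mean / SD (missing when the SD is 0).
    """
    t1 = panels.session_mean(contrast, 1)
    mean_beta = t1.mean(axis=0, skipna=True)
    sd_beta = t1.std(axis=0, ddof=1, skipna=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = mean_beta / sd_beta
    d[sd_beta == 0] = np.nan

    out = pd.DataFrame({
        "parcel_id": t1.columns,
        "mean_beta": mean_beta.to_numpy(),
        "sd_beta": sd_beta.to_numpy(),
        "cohens_d": d.to_numpy(),
        "cortical": [str(p).startswith("CTX") for p in t1.columns],
    })
    icc = icc_table.set_index("parcel_id")["icc"]
    out["icc"] = out["parcel_id"].map(icc).to_numpy()
    if familiality_table is not None:
        fam = familiality_table.set_index("parcel_id")["icc"]
        out["familiality"] = out["parcel_id"].map(fam).to_numpy()
    return out


_FACTOR_COLUMNS = ["icc", "cohens_d", "mean_beta", "sd_beta", "familiality"]


def factor_correlations(
    table: pd.DataFrame,
    stratum: str = "cortical",
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (and two-sided p-values) between the
    factor columns across parcels of one stratum ('cortical',
    'subcortical' or 'all')."""
    if stratum == "cortical":
        sub = table[table["cortical"]]
    elif stratum == "subcortical":
        sub = table[~table["cortical"]]
    elif stratum == "all":
        sub = table
    else:
        raise ValueError(f"unknown stratum: {stratum!r}")
    if len(sub) < 10:
        raise ValueError(f"stratum {stratum!r} has {len(sub)} parcels (< 10)")
    cols = columns or [c for c in _FACTOR_COLUMNS if c in sub.columns]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if j <= i:
                continue
            x = sub[ci].astype(float)
            y = sub[cj].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                r.loc[ci, cj] = r.loc[cj, ci] = np.nan
                p.loc[ci, cj] = p.loc[cj, ci] = np.nan
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r.loc[ci, cj] = r.loc[cj, ci] = res.statistic
            p.loc[ci, cj] = p.loc[cj, ci] = res.pvalue
    return r, p


def compare_icc_sets(
    icc_a: pd.Series | np.ndarray,
    icc_b: pd.Series | np.ndarray,
    *,
    label_a: str = "a",
    label_b: str = "b",
) -> dict:
    """Paired two-sided t-test of Fisher-z transformed ICCs across parcels.

    Raw mean ICCs of each set are reported on the untransformed scale; the
    inference runs on z = atanh(ICC).  Antisymmetric: swapping the sets
    negates t.
    """
    a = pd.Series(np.asarray(icc_a, dtype=float))
    b = pd.Series(np.asarray(icc_b, dtype=float))
    if len(a) != len(b):
        raise ValueError("ICC sets must cover the same parcels")
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared parcels with defined ICCs")
    za = fisher_z(a[ok].to_numpy())
    zb = fisher_z(b[ok].to_numpy())
    if np.allclose(za, zb):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(za, zb)
    return {
        "label_a": label_a, "label_b": label_b,
        "n_parcels": int(ok.sum()),
        "mean_icc_a": float(a[ok].mean()), "mean_icc_b": float(b[ok].mean()),
        "t": float(t), "p": float(p),
    }


def motion_stability(
    panels, *, contrast: str, min_subjects: int = 5
) -> tuple[pd.DataFrame, float, float]:
    """Per-subject between-session instability vs head motion.

    disparity_i = mean over parcels of |run-averaged beta(T1) -
    run-averaged beta(T2)|; motion_i = the subject's relative RMS motion
    averaged over runs and sessions.  Returns the per-subject records and
    the Pearson (r, p) across subjects with both sessions.
    """
    t1 = panels.session_mean(contrast, 1)
    t2 = panels.session_mean(contrast, 2)
    diff = (t1 - t2).abs()
    disparity = diff.mean(axis=1, skipna=True)
    has_both = diff.notna().any(axis=1)
    motion = panels.mean_motion().reindex(disparity.index)

    rec = pd.DataFrame({
        "subject_id": disparity.index,
        "mean_motion_mm": motion.to_numpy(),
        "mean_abs_beta_diff": disparity.to_numpy(),
    })
    ok = has_both & motion.notna()
    if int(ok.sum()) < min_subjects:
        raise ValueError(
            f"only {int(ok.sum())} subjects with both sessions (< {min_subjects})"
        )
    res = stats.pearsonr(rec.loc[ok.to_numpy(), "mean_motion_mm"],
                         rec.loc[ok.to_numpy(), "mean_abs_beta_diff"])
    return rec, float(res.statistic), float(res.pvalue)
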