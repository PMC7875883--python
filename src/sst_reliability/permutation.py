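"""Max-statistic permutation significance for families of ICCs.

Family-wise error across many targets (behavioral variables, whole-brain
parcels, or selected ROIs) is controlled by permutation: in each of B
permutations the Time2 rows (or, for familiality, the twin-2 rows) are
randomly reassigned to subjects (pairs), every target's ICC is recomputed,
and the maximum across targets is recorded.  An observed ICC is significant
iff it is >= the 95th quantile of this null-max distribution; per-target
p-values use the add-one rule p = (1 + #{null_max >= observed}) / (B + 1).

Permutations are drawn uniformly with replacement from the permutation
group (the identity may occur); complete-case filtering is re-applied per
target after every relabeling.  Families are permuted separately, as the
analysis families are separate multiple-testing problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .icc import icc_columns

__all__ = ["PermutationResult", "max_statistic_permutation",
           "permute_trr", "permute_familiality"]


@dataclass
class PermutationResult:
    targets: list[str]
    observed: np.ndarray  # per-target ICC
    null_max: np.ndarray  # valid permutation maxima (length <= B)
    threshold: float  # ceil(0.95 B)-th order statistic of null_max
    p: np.ndarray  # per-target add-one p-values
    significant: np.ndarray  # observed >= threshold
    B: int
    seed: int | None
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "target": self.targets,
            "icc": self.observed,
            "p": self.p,
            "significant": self.significant,
        })


def _threshold(null_max: np.ndarray, alpha: float) -> float:
    """Conservative (1-alpha) quantile: the ceil((1-alpha)*B)-th order
    statistic of the B null maxima."""
    b = null_max.size
    k = math.ceil((1.0 - alpha) * b)
    k = min(max(k, 1), b)
    return float(np.sort(null_max)[k - 1])


def max_statistic_permutation(
    x1: pd.DataFrame | np.ndarray,
    x2: pd.DataFrame | np.ndarray,
    B: int = 5000,
    seed: int | np.random.Generator | None = 0,
    *,
    alpha: float = 0.05,
    min_n: int = 3,
) -> PermutationResult:
    """Permutation test over the columns (targets) of two aligned
    subjects x targets matrices; rows of ``x2`` are relabeled.

    NaNs are allowed; each permutation moves whole rows of ``x2`` (with
    their missingness) and complete-case filtering per column is reapplied.
    Complete (NaN-free) inputs take a vectorised path in which only the
    cross-products need recomputing per permutation.
    """
    if isinstance(x1, pd.DataFrame):
        targets = [str(c) for c in x1.columns]
        a = x1.to_numpy(dtype=float)
    else:
        a = np.asarray(x1, dtype=float)
        targets = [f"t{i}" for i in range(a.shape[1])]
    b_mat = x2.to_numpy(dtype=float) if isinstance(x2, pd.DataFrame) else np.asarray(x2, dtype=float)
    if a.shape != b_mat.shape:
        raise ValueError("x1 and x2 must be aligned (same shape)")
    n = a.shape[0]
    if n < min_n:
        raise ValueError(f"need at least {min_n} subjects, got {n}")
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < math.ceil(1.0 / alpha) - 1:
        import warnings
        warnings.warn(
            f"B={B} is too small to resolve alpha={alpha}; "
            "the threshold will be the sample maximum", stacklevel=2)

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    rng = np.random.default_rng(seed)
    observed = icc_columns(a, b_mat, min_n=min_n)

    if not (np.isnan(a).any() or np.isnan(b_mat).any()):
        null_max = _null_max_complete(a, b_mat, B, rng)
    else:
        null_max = np.empty(B)
        for i in range(B):
            perm = rng.permutation(n)
            icc = icc_columns(a, b_mat[perm], min_n=min_n)
            finite = icc[np.isfinite(icc)]
            # a relabeling under which no target is estimable contributes
            # nothing to the null
            null_max[i] = finite.max() if finite.size else np.nan
        null_max = null_max[np.isfinite(null_max)]

    if null_max.size == 0:
        thr = float("nan")
    else:
        thr = _threshold(null_max, alpha)
    with np.errstate(invalid="ignore"):
        p = (1.0 + (null_max[None, :] >= observed[:, None]).sum(axis=1)) / (
            null_max.size + 1.0)
        p = np.where(np.isnan(observed), np.nan, p)
        significant = np.where(
            np.isnan(observed) | np.isnan(thr), False, observed >= thr)
    return PermutationResult(
        targets, observed, null_max, thr, p, significant.astype(bool), B,
        seed_val, alpha,
    )


def _null_max_complete(
    a: np.ndarray, b: np.ndarray, B: int, rng: np.random.Generator,
    chunk: int = 128,
) -> np.ndarray:
    """Fast path for NaN-free data.

    Column means and the per-column sums of squares Sxx, Syy are invariant
    under row permutation of ``b``, so only the cross-products Sxy change:
    icc_b = 2 * Sxy_b / (Sxx + Syy), batched with einsum over permutations.
    """
    n, p = a.shape
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sxx = (ac * ac).sum(axis=0)
    syy = (bc * bc).sum(axis=0)
    denom = sxx + syy
    ok = denom > 0
    null_max = np.empty(B)
    done = 0
    while done < B:
        m = min(chunk, B - done)
        # m random permutations of the n row labels
        perms = np.argsort(rng.random((m, n)), axis=1)
        sxy = np.einsum("np,mnp->mp", ac, bc[perms], optimize=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            icc = 2.0 * sxy / denom
        icc[:, ~ok] = np.nan
        null_max[done:done + m] = np.nanmax(icc, axis=1)
        done += m
    return null_max


def permute_trr(
    panels,
    contrast: str,
    B: int = 5000,
    seed: int | np.random.Generator | None = 0,
    *,
    design: str = "between_session_full",
    run: int | None = None,
    alpha: float = 0.05,
) -> PermutationResult:
    """Test-retest significance: relabel whole Time2 subject rows (without
    regard to twinship) and rebuild the null-max ICC distribution."""
    if design == "between_session_full":
        x1 = panels.session_mean(contrast, 1)
        x2 = panels.session_mean(contrast, 2)
    elif design == "between_session_run":
        x1 = panels.get(contrast, 1, run)
        x2 = panels.get(contrast, 2, run)
    else:
        raise ValueError(f"unsupported design for TRR permutation: {design!r}")
    x1, x2 = x1.align(x2, join="inner", axis=0)
    return max_statistic_permutation(x1, x2, B, seed, alpha=alpha)


def permute_familiality(
    panels,
    contrast: str,
    B: int = 5000,
    seed: int | np.random.Generator | None = 0,
    *,
    session: int = 1,
    alpha: float = 0.05,
) -> PermutationResult:
    """Familiality significance: randomly permute the sibship assignment of
    twin 2 across pairs and rebuild the null-max twin-ICC distribution."""
    t1, t2 = panels.twin_frames(contrast, session)
    return max_statistic_permutation(t1, t2, B, seed, alpha=alpha)
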