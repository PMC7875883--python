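"""Synthetic parcel-level activation panels for MZ twin pairs.

Emulates the study data that every downstream stage consumes: activation
beta weights for 379 brain parcels (360 cortical + 19 subcortical) per
subject, contrast (correct-stop vs correct-go, incorrect-stop vs
correct-go), session (Time1/Time2) and run (1/2), for a cohort of
monozygotic twin pairs with a per-subject head-motion trait.

Generative model (per contrast), all components independent Gaussians:

    beta(i, p, t, r) = mu(p) + a(pair(i), p) + u(i, p) + s(i, p, t)
                       + eps(i, p, t, r)

* a  ~ N(0, sigma_fam^2)   pair-shared (familial) component
* u  ~ N(0, sigma_subj^2)  stable individual component
* s  ~ N(0, sigma_sess^2)  session (state) component
* eps ~ N(0, [sigma_run * (1 + kappa_motion * m_i)]^2)  run noise, inflated
  by the subject's motion trait m_i ~ lognormal (constant across sessions:
  motion is treated as a stable trait)

"Cleaned" mode emulates data-driven denoising (ICA-FIX-like): sigma_run is
multiplied by ``clean_factor`` and the motion coupling by
``clean_factor_kappa`` (default 0 -- the structured, motion-related part of
the run noise is what such cleaning removes).

The implied ground truth for run-averaged (two-run mean) betas, at
kappa_motion = 0:

    ICC_between = (sigma_fam^2 + sigma_subj^2) / T
    ICC_twin    =  sigma_fam^2 / T
    T = sigma_fam^2 + sigma_subj^2 + sigma_sess^2 + sigma_run^2 / 2
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceSpec",
    "PanelSet",
    "TwinRegistry",
    "generate_panel",
    "apply_dropout",
    "spec_from_icc_targets",
    "CONTRASTS",
]

CONTRASTS = ("stop_vs_go", "error_vs_go")


@dataclass(frozen=True)
class VarianceSpec:
    """Generative variance components (beta units are arbitrary GLM units).

    ``magnitude_coupled`` ties the stable-subject SD to the parcel's |mu|
    (regions with stronger group activation carry larger stable individual
    differences), which induces the positive ICC ~ effect-size correlation
    seen in real task data.
    """

    n_pairs: int = 28
    n_parcels: int = 379
    n_cortical: int | None = None  # default: all but 19 subcortical segments
    mu_mean: float = 0.3
    mu_sd: float = 0.4
    sigma_fam: float = 0.25
    sigma_subj: float = 0.35
    sigma_sess: float = 0.30
    sigma_run: float = 0.55
    kappa_motion: float = 1.5
    clean_factor: float = 0.7
    clean_factor_kappa: float = 0.0
    motion_logmean: float = -1.9  # exp(-1.9) ~ 0.15 mm relative RMS
    motion_logsd: float = 0.4
    magnitude_coupled: bool = True
    contrasts: tuple[str, ...] = CONTRASTS

    def __post_init__(self) -> None:
        for name in ("sigma_fam", "sigma_subj", "sigma_sess", "sigma_run",
                     "kappa_motion", "motion_logsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.clean_factor <= 1.0:
            raise ValueError("clean_factor must be in (0, 1]")
        if not 0.0 <= self.clean_factor_kappa <= 1.0:
            raise ValueError("clean_factor_kappa must be in [0, 1]")
        if self.n_parcels < 1 or self.n_pairs < 1:
            raise ValueError("n_parcels and n_pairs must be >= 1")
        if self.n_cortical is None:
            object.__setattr__(self, "n_cortical", max(self.n_parcels - 19, 0))
        if not 0 <= self.n_cortical <= self.n_parcels:
            raise ValueError("need 0 <= n_cortical <= n_parcels")


@dataclass
class TwinRegistry:
    """Mapping of subjects into MZ pairs with fixed twin-1/twin-2 roles."""

    table: pd.DataFrame  # columns: pair_id, twin1, twin2

    @property
    def pair_ids(self) -> list[str]:
        return list(self.table["pair_id"])

    def twins(self, pair_id: str) -> tuple[str, str]:
        row = self.table.set_index("pair_id").loc[pair_id]
        return str(row["twin1"]), str(row["twin2"])

    def subjects(self) -> list[str]:
        out: list[str] = []
        for _, r in self.table.iterrows():
            out.extend([str(r["twin1"]), str(r["twin2"])])
        return out

    def pair_of(self) -> dict[str, str]:
        d: dict[str, str] = {}
        for _, r in self.table.iterrows():
            d[str(r["twin1"])] = str(r["pair_id"])
            d[str(r["twin2"])] = str(r["pair_id"])
        return d


@dataclass
class PanelSet:
    """Beta panels keyed by (contrast, session, run), subjects x parcels."""

    betas: dict[tuple[str, int, int], pd.DataFrame]
    registry: TwinRegistry
    motion: pd.DataFrame  # subject_id, session, run, rel_rms_mm
    ground_truth: dict
    cleaned: bool = False

    @property
    def subject_ids(self) -> list[str]:
        first = next(iter(self.betas.values()))
        return list(first.index)

    @property
    def parcel_ids(self) -> list[str]:
        first = next(iter(self.betas.values()))
        return list(first.columns)

    @property
    def contrasts(self) -> list[str]:
        return sorted({c for c, _, _ in self.betas})

    @property
    def sessions(self) -> list[int]:
        return sorted({t for _, t, _ in self.betas})

    @property
    def runs(self) -> list[int]:
        return sorted({r for _, _, r in self.betas})

    def get(self, contrast: str, session: int, run: int) -> pd.DataFrame:
        return self.betas[(contrast, session, run)]

    def session_mean(self, contrast: str, session: int) -> pd.DataFrame:
        """Run-averaged betas for one session (NaN if any run missing,
        matching complete-case run averaging)."""
        frames = [
            df for (c, t, _), df in sorted(self.betas.items())
            if c == contrast and t == session
        ]
        if not frames:
            raise KeyError(f"no runs for contrast={contrast!r} session={session}")
        return sum(frames) / len(frames)

    def mean_motion(self) -> pd.Series:
        """Per-subject motion averaged over runs and sessions (mm)."""
        return self.motion.groupby("subject_id")["rel_rms_mm"].mean()

    def twin_frames(
        self, contrast: str, session: int = 1
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(twin1, twin2) run-averaged beta frames, both indexed by pair_id."""
        m = self.session_mean(contrast, session)
        reg = self.registry.table
        t1 = m.reindex(reg["twin1"].to_numpy())
        t2 = m.reindex(reg["twin2"].to_numpy())
        t1.index = reg["pair_id"].to_numpy()
        t2.index = reg["pair_id"].to_numpy()
        return t1, t2


def _parcel_ids(spec: VarianceSpec) -> list[str]:
    ids = [f"CTX_{i:03d}" for i in range(1, spec.n_cortical + 1)]
    ids += [f"SUB_{i:02d}" for i in range(1, spec.n_parcels - spec.n_cortical + 1)]
    return ids


def _subject_sigma_run(spec: VarianceSpec, motion: np.ndarray, cleaned: bool) -> np.ndarray:
    sr = spec.sigma_run * (spec.clean_factor if cleaned else 1.0)
    kappa = spec.kappa_motion * (spec.clean_factor_kappa if cleaned else 1.0)
    return sr * (1.0 + kappa * motion)


def theoretical_icc(spec: VarianceSpec, cleaned: bool = False) -> dict[str, float]:
    """Closed-form between-session and twin ICC of run-averaged betas at
    kappa_motion = 0 (homogeneous-parcel case, magnitude coupling off)."""
    sr = spec.sigma_run * (spec.clean_factor if cleaned else 1.0)
    total = spec.sigma_fam**2 + spec.sigma_subj**2 + spec.sigma_sess**2 + sr**2 / 2
    return {
        "icc_between_session": (spec.sigma_fam**2 + spec.sigma_subj**2) / total,
        "icc_twin": spec.sigma_fam**2 / total,
    }


def generate_panel(
    spec: VarianceSpec,
    cleaned: bool = False,
    seed: int | np.random.Generator | None = 0,
    *,
    n_sessions: int = 2,
    n_runs: int = 2,
) -> PanelSet:
    """Draw a full panel set with known ground truth.

    The same seed yields the same latent components whether or not
    ``cleaned`` is set -- pass the same seed with ``cleaned`` toggled to get
    before/after-denoising versions of the same cohort (only the run-noise
    scale differs; the noise draws themselves are shared standard normals).
    """
    rng = np.random.default_rng(seed)
    n_subj = 2 * spec.n_pairs
    pair_ids = [f"P{i:03d}" for i in range(1, spec.n_pairs + 1)]
    subj_ids = [f"S{i:03d}" for i in range(1, n_subj + 1)]
    reg = TwinRegistry(pd.DataFrame({
        "pair_id": pair_ids,
        "twin1": subj_ids[0::2],
        "twin2": subj_ids[1::2],
    }))
    parcels = _parcel_ids(spec)
    pair_index = np.repeat(np.arange(spec.n_pairs), 2)

    motion_trait = rng.lognormal(spec.motion_logmean, spec.motion_logsd, n_subj)
    sigma_run_i = _subject_sigma_run(spec, motion_trait, cleaned)

    betas: dict[tuple[str, int, int], pd.DataFrame] = {}
    gt_parcel: dict[str, dict[str, np.ndarray]] = {}
    for contrast in spec.contrasts:
        mu = spec.mu_mean + spec.mu_sd * rng.standard_normal(spec.n_parcels)
        if spec.magnitude_coupled and spec.mu_sd > 0:
            scale = np.abs(mu) / np.sqrt(np.mean(mu**2))
            sigma_subj_p = spec.sigma_subj * scale
        else:
            sigma_subj_p = np.full(spec.n_parcels, spec.sigma_subj)

        a = spec.sigma_fam * rng.standard_normal((spec.n_pairs, spec.n_parcels))
        u = sigma_subj_p * rng.standard_normal((n_subj, spec.n_parcels))
        s = spec.sigma_sess * rng.standard_normal((n_subj, spec.n_parcels, n_sessions))
        base = mu[None, :] + a[pair_index] + u
        for t in range(1, n_sessions + 1):
            for r in range(1, n_runs + 1):
                eps = rng.standard_normal((n_subj, spec.n_parcels))
                vals = base + s[:, :, t - 1] + sigma_run_i[:, None] * eps
                betas[(contrast, t, r)] = pd.DataFrame(
                    vals, index=subj_ids, columns=parcels
                )

        sr0 = spec.sigma_run * (spec.clean_factor if cleaned else 1.0)
        total_p = (spec.sigma_fam**2 + sigma_subj_p**2 + spec.sigma_sess**2
                   + sr0**2 / n_runs)
        gt_parcel[contrast] = {
            "icc_between_session": (spec.sigma_fam**2 + sigma_subj_p**2) / total_p,
            "icc_twin": np.full(spec.n_parcels, spec.sigma_fam**2) / total_p,
            "mu": mu,
        }

    motion_rows = []
    for t in range(1, n_sessions + 1):
        for r in range(1, n_runs + 1):
            for sid, m in zip(subj_ids, motion_trait):
                motion_rows.append(
                    {"subject_id": sid, "session": t, "run": r, "rel_rms_mm": m}
                )
    motion = pd.DataFrame(motion_rows)

    ground_truth = {
        "theoretical": theoretical_icc(spec, cleaned),
        "per_parcel": {
            c: {k: np.asarray(v).tolist() for k, v in d.items()}
            for c, d in gt_parcel.items()
        },
        "cleaned": cleaned,
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(spec).items()
        },
    }
    return PanelSet(betas, reg, motion, ground_truth, cleaned)


def apply_dropout(
    panels: PanelSet,
    n_return: int,
    seed: int | np.random.Generator | None = 0,
    *,
    n_complete_pairs: int | None = None,
) -> PanelSet:
    """Mark Time2 data missing for subjects who did not return.

    With ``n_complete_pairs`` given, exactly that many pairs return intact
    and the remaining returnees are single twins from distinct pairs
    (emulating e.g. 44 of 56 subjects returning with 19 of 27 pairs
    complete); otherwise returnees are drawn uniformly at random, which
    preserves some complete pairs by chance.
    """
    rng = np.random.default_rng(seed)
    subjects = panels.subject_ids
    if n_return > len(subjects):
        raise ValueError("n_return exceeds the cohort size")
    if n_return == len(subjects):
        return panels

    if n_complete_pairs is None:
        keep = set(rng.choice(subjects, size=n_return, replace=False))
    else:
        reg = panels.registry.table
        n_singles = n_return - 2 * n_complete_pairs
        if n_singles < 0 or n_complete_pairs > len(reg):
            raise ValueError("n_complete_pairs incompatible with n_return")
        if n_singles > len(reg) - n_complete_pairs:
            raise ValueError("not enough broken pairs to supply single twins")
        order = rng.permutation(len(reg))
        keep = set()
        for i in order[:n_complete_pairs]:
            keep.add(str(reg.iloc[i]["twin1"]))
            keep.add(str(reg.iloc[i]["twin2"]))
        for i in order[n_complete_pairs:n_complete_pairs + n_singles]:
            col = "twin1" if rng.random() < 0.5 else "twin2"
            keep.add(str(reg.iloc[i][col]))

    betas = {}
    dropped = [s for s in subjects if s not in keep]
    for key, df in panels.betas.items():
        df = df.copy()
        if key[1] == 2:  # Time2
            df.loc[dropped, :] = np.nan
        betas[key] = df
    motion = panels.motion.copy()
    drop_mask = (motion["session"] == 2) & motion["subject_id"].isin(dropped)
    motion.loc[drop_mask, "rel_rms_mm"] = np.nan
    return PanelSet(betas, panels.registry, motion, panels.ground_truth,
                    panels.cleaned)


def spec_from_icc_targets(
    icc_between: float,
    icc_twin: float,
    *,
    sess_run_split: float = 0.5,
    total_var: float = 1.0,
    **overrides,
) -> VarianceSpec:
    """Build a VarianceSpec whose theoretical run-averaged between-session
    and twin ICCs equal the requested values (at kappa_motion = 0).

    The residual (1 - icc_between) share of the total variance is split
    between the session component and the run-averaged noise according to
    ``sess_run_split`` (fraction going to sigma_sess^2).
    """
    if not 0.0 <= icc_twin <= icc_between < 1.0:
        raise ValueError("need 0 <= icc_twin <= icc_between < 1")
    var_fam = icc_twin * total_var
    var_subj = (icc_between - icc_twin) * total_var
    resid = (1.0 - icc_between) * total_var
    var_sess = sess_run_split * resid
    var_run_avg = (1.0 - sess_run_split) * resid  # = sigma_run^2 / 2
    defaults = dict(
        sigma_fam=np.sqrt(var_fam),
        sigma_subj=np.sqrt(var_subj),
        sigma_sess=np.sqrt(var_sess),
        sigma_run=np.sqrt(2.0 * var_run_avg),
        kappa_motion=0.0,
        magnitude_coupled=False,
    )
    defaults.update(overrides)
    return VarianceSpec(**defaults)
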