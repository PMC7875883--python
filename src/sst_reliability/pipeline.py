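"""End-to-end pipeline: simulate, preprocess, estimate, report.

Stage order mirrors the study's analysis chain: simulate behavior ->
simulate neural panels -> iterative outlier exclusion (+ missingness
propagation) -> test-retest ICCs -> familiality ICCs -> max-statistic
permutation significance -> factor analyses.  Every stage draws its
randomness from a named seed in the config and logs subject/parcel counts,
so a rerun with the same config reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, factors, io, outliers, permutation, synth
from . import task as sst
from .icc import batch_icc, icc_columns, classify_icc

__all__ = ["AnalysisConfig", "PipelineConfig", "run_pipeline"]

log = logging.getLogger("sst_reliability")


@dataclass(frozen=True)
class AnalysisConfig:
    """Switches for the inference chain."""

    n_permutations: int = 1000
    z_cut: float = 3.0
    n_outlier_iter: int = 10
    ssrt_method: str = "integration"
    cleaned: bool = False
    alpha: float = 0.05
    n_behavior_subjects: int = 56
    n_return: int = 44
    n_complete_pairs_return: int = 19


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    task: sst.TaskConfig = field(default_factory=sst.TaskConfig)
    race: sst.RaceModelParams = field(default_factory=sst.RaceModelParams)
    variance: synth.VarianceSpec = field(default_factory=synth.VarianceSpec)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = dataclasses.asdict(self)
        d["variance"]["contrasts"] = list(d["variance"]["contrasts"])
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        var = dict(d.get("variance", {}))
        if "contrasts" in var:
            var["contrasts"] = tuple(var["contrasts"])
        return cls(
            seed=d.get("seed", 0),
            task=sst.TaskConfig(**d.get("task", {})),
            race=sst.RaceModelParams(**d.get("race", {})),
            variance=synth.VarianceSpec(**var),
            analysis=AnalysisConfig(**d.get("analysis", {})),
        )


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage_seed(seed: int, stage: int) -> int:
    # distinct, reproducible per-stage streams, kept below 2**31
    return int((seed * 1000 + stage) % (2**31 - 1))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the result bundle under ``outdir``.

    Returns a dict with the key tables (behavioral comparison, per-parcel
    ICCs, permutation results, factor table) and the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.analysis
    bundle: dict = {"paths": {}}

    # --- stage 1: behavior ------------------------------------------------
    stage = "simulate-behavior"
    log.info("[%s] %d subjects x 2 sessions", stage, cfg.n_behavior_subjects)
    summaries: dict[int, list[behavior.BehavioralSummary]] = {1: [], 2: []}
    for i in range(cfg.n_behavior_subjects):
        sid = f"S{i + 1:03d}"
        for ses in (1, 2):
            if ses == 2 and i >= cfg.n_return:
                continue
            logs = sst.simulate_session(
                config.race, config.task,
                _stage_seed(config.seed, 1) + 7919 * i + ses,
                subject_id=sid, session=ses,
            )
            summaries[ses].append(
                behavior.summarize_subject(logs, cfg.ssrt_method)
            )
    frame_t1 = behavior.summaries_to_frame(summaries[1])
    frame_t2 = behavior.summaries_to_frame(summaries[2])

    # --- stage 2: behavioral outlier exclusion + session comparison -------
    stage = "behavioral-metrics"
    try:
        b1, rep1 = outliers.exclude_outliers_frame(
            frame_t1.set_index("subject_id")[behavior.VARIABLES],
            cfg.z_cut, cfg.n_outlier_iter)
        rep2: list = []
        if len(frame_t2):
            b2, rep2 = outliers.exclude_outliers_frame(
                frame_t2.set_index("subject_id")[behavior.VARIABLES],
                cfg.z_cut, cfg.n_outlier_iter)
            b1, b2 = outliers.propagate_missing_timepoints(b1, b2)
            behav_table = behavior.compare_sessions(b1, b2)
            behav_icc = icc_columns(
                b1.reindex(b2.index).to_numpy(), b2.to_numpy())
            behav_table["trr_icc"] = behav_table["variable"].map(
                dict(zip(behavior.VARIABLES, behav_icc)))
        else:
            behav_table = pd.DataFrame({
                "variable": behavior.VARIABLES,
                "time1_mean": b1.mean().to_numpy(),
                "time1_sd": b1.std(ddof=1).to_numpy(),
                "note": "no Time2 sample",
            })
        pct = 100.0 * sum(r.total_excluded for r in rep1 + rep2) / max(
            sum(r.n_input for r in rep1 + rep2), 1)
        log.info("[%s] excluded %.2f%% behavioral datapoints", stage, pct)
        p = outdir / "behavioral_summary.csv"
        behav_table.to_csv(p, index=False)
        bundle["behavioral_table"] = behav_table
        bundle["paths"]["behavioral_table"] = str(p)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage} failed: {e}") from e

    # --- stage 3: neural panels -------------------------------------------
    stage = "simulate-neural"
    panels = synth.generate_panel(
        config.variance, cleaned=cfg.cleaned, seed=_stage_seed(config.seed, 3))
    panels = synth.apply_dropout(
        panels, cfg.n_return, _stage_seed(config.seed, 4),
        n_complete_pairs=cfg.n_complete_pairs_return)
    log.info("[%s] %d subjects x %d parcels, cleaned=%s", stage,
             len(panels.subject_ids), len(panels.parcel_ids), cfg.cleaned)
    io.write_panel_set(panels, outdir / "panels")
    bundle["paths"]["panels"] = str(outdir / "panels")

    # --- stage 4: neural outlier exclusion + propagation -------------------
    stage = "preprocess"
    try:
        excl_report = {}
        for key in list(panels.betas):
            df = panels.betas[key]
            ses = key[1]
            present = df.dropna(how="all")
            if len(present) < 3:  # e.g. an empty Time2 sample
                excl_report["{}:{}:{}".format(*key)] = {
                    "n_values": 0, "n_excluded": 0}
                continue
            cleaned_df, reps = outliers.exclude_outliers_frame(
                present, cfg.z_cut, cfg.n_outlier_iter)
            out = df.copy()
            out.loc[cleaned_df.index, :] = cleaned_df
            panels.betas[key] = out
            excl_report["{}:{}:{}".format(*key)] = {
                "n_values": int(sum(r.n_input for r in reps)),
                "n_excluded": int(sum(r.total_excluded for r in reps)),
            }
        total_in = sum(v["n_values"] for v in excl_report.values())
        total_ex = sum(v["n_excluded"] for v in excl_report.values())
        log.info("[%s] excluded %.2f%% of beta values", stage,
                 100.0 * total_ex / max(total_in, 1))
        with open(outdir / "outlier_report.json", "w") as fh:
            json.dump(excl_report, fh, indent=1)
        bundle["paths"]["outlier_report"] = str(outdir / "outlier_report.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage} failed: {e}") from e

    # --- stage 5/6: TRR + familiality + permutation -------------------------
    contrast_results = {}
    for contrast in config.variance.contrasts:
        stage = f"trr:{contrast}"
        try:
            x1 = panels.session_mean(contrast, 1)
            x2 = panels.session_mean(contrast, 2)
            x1p, x2p = outliers.propagate_missing_timepoints(x1, x2)
            # only subjects with data at both sessions enter the relabeling
            both = ~(x1p.isna().all(axis=1)) & ~(x2p.isna().all(axis=1))
            n_complete = int(both.sum())
            if n_complete < 3:
                raise PipelineError(
                    f"stage {stage}: only {n_complete} subjects with both "
                    "sessions after dropout/exclusion")
            x1p, x2p = x1p.loc[both], x2p.loc[both]
            perm = permutation.max_statistic_permutation(
                x1p, x2p, cfg.n_permutations,
                _stage_seed(config.seed, 5), alpha=cfg.alpha)
            trr_table = perm.to_frame().rename(columns={"target": "parcel_id"})
            trr_table["category"] = [
                classify_icc(v) if np.isfinite(v) else "undefined"
                for v in trr_table["icc"]
            ]
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage {stage} failed: {e}") from e

        stage = f"familiality:{contrast}"
        try:
            t1, t2 = panels.twin_frames(contrast, 1)
            fperm = permutation.max_statistic_permutation(
                t1, t2, cfg.n_permutations,
                _stage_seed(config.seed, 6), alpha=cfg.alpha)
            fam_table = fperm.to_frame().rename(columns={"target": "parcel_id"})
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage {stage} failed: {e}") from e

        stage = f"factors:{contrast}"
        try:
            ftable = factors.build_factor_table(
                panels, trr_table, fam_table, contrast=contrast)
            corr_r, corr_p = factors.factor_correlations(ftable, "cortical")
            within = [
                batch_icc(panels, "within_session", contrast=contrast, session=t)
                for t in (1, 2)
            ]
            within_mean = np.nanmean(
                np.vstack([w["icc"].to_numpy() for w in within]), axis=0)
            between_runs = [
                batch_icc(panels, "between_session_run", contrast=contrast, run=r)
                for r in (1, 2)
            ]
            between_mean = np.nanmean(
                np.vstack([b["icc"].to_numpy() for b in between_runs]), axis=0)
            duration_cmp = factors.compare_icc_sets(
                between_runs[0]["icc"], trr_table["icc"],
                label_a="run1_only", label_b="both_runs")
            interval_cmp = factors.compare_icc_sets(
                within_mean, between_mean,
                label_a="within_session", label_b="between_session")
            motion_rec, motion_r, motion_p = factors.motion_stability(
                panels, contrast=contrast)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage {stage} failed: {e}") from e

        tag = contrast
        trr_table.to_csv(outdir / f"trr_{tag}.csv", index=False)
        fam_table.to_csv(outdir / f"familiality_{tag}.csv", index=False)
        ftable.to_csv(outdir / f"factor_table_{tag}.csv", index=False)
        corr_r.to_csv(outdir / f"factor_corr_r_{tag}.csv")
        motion_rec.to_csv(outdir / f"motion_stability_{tag}.csv", index=False)
        with open(outdir / f"comparisons_{tag}.json", "w") as fh:
            json.dump({
                "retest_interval": interval_cmp,
                "task_duration": duration_cmp,
                "motion_r": motion_r, "motion_p": motion_p,
            }, fh, indent=1)
        contrast_results[contrast] = {
            "trr": trr_table, "familiality": fam_table, "factors": ftable,
            "factor_corr_r": corr_r, "factor_corr_p": corr_p,
            "interval_comparison": interval_cmp,
            "duration_comparison": duration_cmp,
            "motion": (motion_rec, motion_r, motion_p),
        }
        log.info("[trr:%s] %d/%d parcels significant (threshold %.3f)",
                 contrast, int(trr_table["significant"].sum()),
                 len(trr_table), perm.threshold)

    bundle["contrasts"] = contrast_results
    bundle["panels"] = panels
    return bundle
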