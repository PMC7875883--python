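"""Delimited-text readers and writers for the analysis artifacts.

Beta matrices are stored one file per contrast x session x run as CSV with
an index column of subject ids and a header row of parcel ids; missing
values are empty fields.  Twin registries, motion summaries and per-parcel
result tables are plain CSV; ground truth and reports are JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import PanelSet, TwinRegistry

__all__ = [
    "write_beta_matrix",
    "read_beta_matrix",
    "write_panel_set",
    "read_panel_set",
    "write_registry",
    "read_registry",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed delimited input (carries the offending line number)."""


def write_beta_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a subjects x parcels frame; NaN becomes an empty field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index_label="subject_id", na_rep="")
    return path


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a beta matrix, validating shape and id uniqueness.

    Raises :class:`ParseError` (with the 1-based line number) for ragged
    rows or duplicate subject/parcel ids.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (line 1)")
        parcels = header[1:]
        if len(set(parcels)) != len(parcels):
            raise ParseError(f"{path}: duplicate parcel ids in header (line 1)")
        rows, index = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            index.append(row[0])
            rows.append([float(v) if v != "" else np.nan for v in row[1:]])
    if len(set(index)) != len(index):
        raise ParseError(f"{path}: duplicate subject ids")
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"),
                        columns=parcels, dtype=float)


def write_registry(registry: TwinRegistry, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    registry.table.to_csv(path, index=False)
    return path


def read_registry(path: str | Path) -> TwinRegistry:
    table = pd.read_csv(path, dtype=str)
    required = {"pair_id", "twin1", "twin2"}
    if not required.issubset(table.columns):
        raise ParseError(f"{path}: registry needs columns {sorted(required)}")
    return TwinRegistry(table)


def _panel_filename(contrast: str, session: int, run: int) -> str:
    return f"betas_{contrast}_ses-{session}_run-{run}.csv"


def write_panel_set(panels: PanelSet, outdir: str | Path) -> dict[str, str]:
    """Write a full panel set (beta matrices, registry, motion, ground
    truth) into ``outdir``; returns the map of artifact names to paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for (c, t, r), df in sorted(panels.betas.items()):
        p = write_beta_matrix(df, outdir / _panel_filename(c, t, r))
        paths[f"betas:{c}:{t}:{r}"] = str(p)
    paths["registry"] = str(write_registry(panels.registry, outdir / "twin_registry.csv"))
    motion_path = outdir / "motion.csv"
    panels.motion.to_csv(motion_path, index=False)
    paths["motion"] = str(motion_path)
    gt_path = outdir / "ground_truth.json"
    with open(gt_path, "w") as fh:
        json.dump(panels.ground_truth, fh, indent=1)
    paths["ground_truth"] = str(gt_path)
    return paths


def read_panel_set(indir: str | Path) -> PanelSet:
    """Reassemble a panel set written by :func:`write_panel_set`."""
    indir = Path(indir)
    betas: dict[tuple[str, int, int], pd.DataFrame] = {}
    for p in sorted(indir.glob("betas_*_ses-*_run-*.csv")):
        stem = p.stem[len("betas_"):]
        contrast, ses_part, run_part = stem.rsplit("_", 2)
        t = int(ses_part.split("-")[1])
        r = int(run_part.split("-")[1])
        betas[(contrast, t, r)] = read_beta_matrix(p)
    if not betas:
        raise ParseError(f"{indir}: no beta matrices found")
    registry = read_registry(indir / "twin_registry.csv")
    motion = pd.read_csv(indir / "motion.csv")
    gt_path = indir / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return PanelSet(betas, registry, motion, ground_truth,
                    bool(ground_truth.get("cleaned", False)))
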