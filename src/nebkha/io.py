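"""Patch-table CSV and configuration I/O.

The exchange format is a plain CSV with header ``id,x,y,diameter`` and an
optional ``cohort`` column (units meters, decimal point, UTF-8).  Loading
validates every row (positive diameter, whole-disc containment, global
non-overlap), classifies patches into cohorts when the column is absent,
and reports violations with their line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    COHORTS,
    PatchPattern,
    RectWindow,
    classify_cohorts,
    validate_patterns,
)
from .pipeline import AnalysisConfig

__all__ = [
    "LoadReport",
    "load_patch_table",
    "save_patch_table",
    "load_config",
]

REQUIRED_COLUMNS = ("id", "x", "y", "diameter")


@dataclass
class LoadReport:
    n_rows: int = 0
    n_patches: int = 0
    per_cohort: dict[str, int] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)


def load_patch_table(
    path: str | Path,
    window: RectWindow,
    classify: bool | None = None,
) -> tuple[dict[str, PatchPattern], LoadReport]:
    """Read a patch table and split it into per-cohort patterns.

    Raises ``ValueError`` on malformed rows (with line numbers), on discs
    extending outside the window, and on overlapping discs in the input.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    report = LoadReport(n_rows=len(df))
    # header is line 1; data row i sits on line i + 2
    for col in ("x", "y", "diameter"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ValueError(f"{path}: non-numeric {col!r} on line {bad[0] + 2}")
        df[col] = vals
    bad = np.flatnonzero(~(df["diameter"].to_numpy() > 0))
    if bad.size:
        raise ValueError(
            f"{path}: non-positive diameter "
            f"{df['diameter'].iloc[bad[0]]} on line {bad[0] + 2}"
        )
    if classify is None:
        classify = "cohort" not in df.columns
    if classify:
        df = df.assign(cohort=classify_cohorts(df["diameter"].to_numpy()))
    unknown = set(df["cohort"]) - set(COHORTS)
    if unknown:
        raise ValueError(f"{path}: unknown cohort labels {sorted(unknown)}")
    patterns: dict[str, PatchPattern] = {}
    for label in COHORTS:
        sub = df[df["cohort"] == label]
        pat = PatchPattern(
            window,
            sub["x"].to_numpy(float),
            sub["y"].to_numpy(float),
            sub["diameter"].to_numpy(float),
            sub["id"].to_numpy(int),
            label,
        )
        patterns[label] = pat
        report.per_cohort[label] = len(pat)
    nonempty = [p for p in patterns.values() if len(p)]
    for p in nonempty:
        inside = window.contains_disc(p.x, p.y, p.radius)
        if not np.all(inside):
            i = np.flatnonzero(~inside)[0]
            raise ValueError(
                f"{path}: patch id {int(p.ids[i])} extends outside the window"
            )
    validate_patterns(nonempty)
    report.n_patches = int(sum(len(p) for p in patterns.values()))
    return patterns, report


def save_patch_table(
    patterns: Mapping[str, PatchPattern] | PatchPattern, path: str | Path
) -> None:
    """Write patterns back to the patch-table CSV format."""
    if isinstance(patterns, PatchPattern):
        frames = [patterns.to_dataframe()]
    else:
        frames = [p.to_dataframe() for p in patterns.values() if len(p)]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=[*REQUIRED_COLUMNS, "cohort"])
    )
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)
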