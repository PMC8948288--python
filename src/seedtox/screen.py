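"""Arrayed viability-screen analytics.

A 6mer-seed screen transfects each of the 4096 possible seeds (embedded in
a neutral siRNA backbone) into cells arrayed over plates grouped into sets,
with non-targeting control wells (e.g. siNT1) in every set, and reads out
luminescence proportional to ATP content ~96 h later. Analysis normalizes
each well to its own set's control mean (set effects cancel before any
averaging), averages replicates, ranks seeds by averaged percent viability
across cell lines, and summarizes positional nucleotide composition of seed
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import RNA_ALPHABET, validate_word

WELL_COLUMNS = [
    "seed",
    "cell_line",
    "set_id",
    "plate_id",
    "replicate",
    "raw_signal",
    "is_control",
    "control_name",
]

HIGHLY_TOXIC_MAX = 10.0  # viability <= 10% i.e. >= 90% reduction
MODERATELY_TOXIC_MAX = 50.0


class MissingControlError(ValueError):
    """A set contains no wells of the requested control."""


class DegenerateControlError(ValueError):
    """A set's control mean is zero or negative."""


@dataclass
class ScreenMatrix:
    """Normalized percent viability per (seed, cell line).

    ``viability`` is a seeds x cell-lines frame (100 = control level);
    missing cells are NaN. ``provenance`` records the control name and the
    per-(cell line, set) control means used.
    """

    viability: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.viability.columns)

    @property
    def seeds(self) -> list[str]:
        return list(self.viability.index)

    def to_csv(self, path: str | Path) -> None:
        self.viability.rename_axis("seed").to_csv(path)


@dataclass
class SeedRanking:
    """Seeds ordered most -> least toxic with 1-based ranks."""

    table: pd.DataFrame  # columns: seed, avg_viability, rank, toxicity_class
    cell_line_subset: list[str] = field(default_factory=list)

    @property
    def seeds(self) -> list[str]:
        return list(self.table["seed"])

    def rank_of(self, seed: str) -> int:
        row = self.table.loc[self.table["seed"] == seed, "rank"]
        if row.empty:
            raise KeyError(seed)
        return int(row.iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class PositionFrequencyMatrix:
    """Positional nucleotide counts of a seed group (6 positions x ACGU)."""

    counts: pd.DataFrame  # index 1..6, columns A,C,G,U
    n_seeds: int

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n_seeds


def read_wells(path: str | Path) -> pd.DataFrame:
    """Read a well-level screen CSV and validate/normalize it."""
    wells = pd.read_csv(path, dtype={"control_name": "string"})
    return validate_wells(wells)


def validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    wells = wells.copy()
    wells["is_control"] = wells["is_control"].astype(bool)
    if (wells["raw_signal"] < 0).any():
        raise ValueError("raw_signal must be >= 0")
    seeds = wells.loc[~wells["is_control"], "seed"]
    wells.loc[~wells["is_control"], "seed"] = [
        validate_word(s, 6) for s in seeds
    ]
    return wells


def normalize_screen(wells: pd.DataFrame, control_name: str = "siNT1") -> ScreenMatrix:
    """Normalize raw luminescence to per-set control means.

    Within each (cell line, set): viability% = 100 * raw / mean(raw of
    control wells named ``control_name``). Replicate wells of a seed within
    a cell line are averaged *after* normalization, then one value per
    (seed, cell line) is returned.
    """
    wells = validate_wells(wells)
    ctrl = wells[wells["is_control"] & (wells["control_name"] == control_name)]
    control_means: dict[tuple[str, str], float] = {}
    normalized = []
    for (cell_line, set_id), grp in wells.groupby(["cell_line", "set_id"], sort=False):
        c = ctrl[(ctrl["cell_line"] == cell_line) & (ctrl["set_id"] == set_id)]
        if c.empty:
            raise MissingControlError(
                f"set {set_id!r} (cell line {cell_line!r}) has no "
                f"{control_name!r} control wells"
            )
        mean = float(c["raw_signal"].mean())
        if mean <= 0:
            raise DegenerateControlError(
                f"control mean for set {set_id!r} (cell line {cell_line!r}) "
                f"is {mean}, cannot normalize"
            )
        control_means[(cell_line, str(set_id))] = mean
        g = grp.copy()
        g["viability"] = 100.0 * g["raw_signal"] / mean
        normalized.append(g)
    norm = pd.concat(normalized, ignore_index=True)
    per_seed = (
        norm[~norm["is_control"]]
        .groupby(["seed", "cell_line"], sort=True)["viability"]
        .mean()
        .unstack("cell_line")
    )
    provenance = {
        "control_name": control_name,
        "control_means": {f"{cl}/{s}": m for (cl, s), m in control_means.items()},
    }
    matrix = ScreenMatrix(per_seed, provenance)
    # control wells themselves carry the normalized values for invariants
    matrix.provenance["control_viability_mean_by_set"] = {
        f"{cl}/{s}": float(
            100.0
            * ctrl[(ctrl["cell_line"] == cl) & (ctrl["set_id"].astype(str) == s)][
                "raw_signal"
            ].mean()
            / m
        )
        for (cl, s), m in control_means.items()
    }
    return matrix


def classify_toxicity(viability_pct: float) -> str:
    """highly_toxic (<=10%), moderately_toxic (<=50%) or non_toxic.

    Thresholds are inclusive: 90%-or-more reduction means viability of
    exactly 10% is still highly toxic.
    """
    if viability_pct < 0:
        raise ValueError(f"viability must be >= 0, got {viability_pct}")
    if viability_pct <= HIGHLY_TOXIC_MAX:
        return "highly_toxic"
    if viability_pct <= MODERATELY_TOXIC_MAX:
        return "moderately_toxic"
    return "non_toxic"


def rank_seeds(
    matrix: ScreenMatrix,
    cell_lines: Sequence[str] | None = None,
    *,
    allow_partial: bool = False,
) -> SeedRanking:
    """Rank seeds most -> least toxic by mean viability over cell lines.

    Average is the unweighted mean across the requested cell lines; ties
    are broken lexicographically by seed so ranking is deterministic.
    Seeds with missing cells raise unless ``allow_partial`` (then the mean
    is over available cell lines only).
    """
    if cell_lines is None:
        cell_lines = matrix.cell_lines
    unknown = [c for c in cell_lines if c not in matrix.viability.columns]
    if unknown:
        raise ValueError(f"unknown cell line(s): {unknown}")
    sub = matrix.viability[list(cell_lines)]
    if sub.isna().any().any() and not allow_partial:
        bad = sub.index[sub.isna().any(axis=1)][:5].tolist()
        raise ValueError(
            f"missing viability cells for seeds {bad} (pass allow_partial=True "
            "to average over available cell lines)"
        )
    avg = sub.mean(axis=1, skipna=allow_partial)
    table = (
        avg.rename("avg_viability")
        .rename_axis("seed")
        .reset_index()
        .sort_values(["avg_viability", "seed"], kind="mergesort")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    table["toxicity_class"] = table["avg_viability"].map(classify_toxicity)
    return SeedRanking(table, list(cell_lines))


def screen_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p between two paired viability vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def nucleotide_composition(seeds: Iterable[str]) -> PositionFrequencyMatrix:
    """Positional nucleotide counts over a group of 6mer seeds."""
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, 7, name="position"), columns=list(RNA_ALPHABET)
    )
    n = 0
    for seed in seeds:
        w = validate_word(seed, 6, name=seed)
        for pos, base in enumerate(w, start=1):
            counts.loc[pos, base] += 1
        n += 1
    return PositionFrequencyMatrix(counts, n)
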