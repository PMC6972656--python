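"""Co-localization statistics from per-cell immunolabelling counts.

Each counted cell carries three boolean labels: candidate marker positive,
HA positive (the RiboTag tag, marking GABA neurons) and TH positive
(tyrosine hydroxylase, marking dopamine neurons).  The animal is the unit
of replication: percentages are computed per animal, then summarized as
mean +/- SEM across animals (SEM = sd of the animal means / sqrt(n)).

Two families of statistics are reported:

* the composition of candidate+ cells across the exclusive classes
  HA-only / TH-only / HA-and-TH / neither (sums to 100% per animal), and
* the fraction of HA+ (and of TH+) cells expressing the candidate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

COMPOSITION_CLASSES = ("ha_only", "th_only", "ha_and_th", "neither")


@dataclass
class CellTable:
    """Per-cell boolean labels with animal ids."""

    frame: pd.DataFrame  # columns: cell_id, animal_id, candidate, ha, th

    def __post_init__(self) -> None:
        required = {"cell_id", "animal_id", "candidate", "ha", "th"}
        if not required <= set(self.frame.columns):
            raise InputError(f"cell table needs columns {sorted(required)}")
        if len(self.frame) == 0:
            raise InputError("cell table is empty")
        dup = self.frame.duplicated(subset=["animal_id", "cell_id"])
        if dup.any():
            raise InputError(
                "duplicate cell ids within an animal: "
                + str(self.frame.loc[dup, ["animal_id", "cell_id"]]
                      .head().to_dict("records")))
        for col in ("candidate", "ha", "th"):
            vals = set(pd.unique(self.frame[col]))
            if not vals <= {0, 1, True, False}:
                raise InputError(f"column {col} must be boolean 0/1, "
                                 f"got {vals}")

    @property
    def animals(self) -> list[str]:
        return sorted(map(str, pd.unique(self.frame["animal_id"])))


def read_cell_table(path) -> CellTable:
    """Parse the cell-count CSV (cell_id, animal_id, candidate, ha, th; 0/1)."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    required = {"cell_id", "animal_id", "candidate", "ha", "th"}
    if not required <= set(df.columns):
        raise InputError(f"cell table needs columns {sorted(required)}")
    for col in ("candidate", "ha", "th"):
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # 1-based + header
            raise InputError(f"non-boolean value in column {col!r} at "
                             f"line(s) {lines[:5]}")
        df[col] = df[col].astype(int)
    return CellTable(df)


def write_cell_table(cells: CellTable, path) -> None:
    out = cells.frame.copy()
    for col in ("candidate", "ha", "th"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


@dataclass
class ColocSummary:
    """Cross-animal co-localization summary.

    ``per_animal`` holds one row per animal and statistic;
    ``means`` maps statistic name -> (mean, sem, n_animals).  Statistics
    whose denominator class is empty in an animal are flagged missing for
    that animal (never reported as 0) and that animal is dropped from the
    cross-animal mean with a warning.
    """

    per_animal: pd.DataFrame
    means: dict[str, tuple[float, float, int]]
    n_cells: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(stat, mean, sem, n, self.n_cells.get(stat, 0))
                for stat, (mean, sem, n) in self.means.items()]
        return pd.DataFrame(rows, columns=["statistic", "mean_percent",
                                           "sem_percent", "n_animals",
                                           "n_cells"])


def _mean_sem(values: list[float]) -> tuple[float, float, int]:
    n = len(values)
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


def summarize_colocalization(cells: CellTable) -> ColocSummary:
    """Per-animal percentages and cross-animal mean +/- SEM.

    Candidate-composition percentages are exclusive and exhaustive over
    candidate+ cells and sum to 100% per animal.
    """
    df = cells.frame.copy()
    for col in ("candidate", "ha", "th"):
        df[col] = df[col].astype(bool)
    animals = cells.animals
    if not animals:
        raise InputError("no animals in cell table")

    records = []
    stats: dict[str, list[float]] = {}
    n_cells: dict[str, int] = {}

    def add(animal: str, stat: str, value: float | None, denom: int) -> None:
        records.append((animal, stat, value, denom))
        if value is not None:
            stats.setdefault(stat, []).append(value)
            n_cells[stat] = n_cells.get(stat, 0) + denom

    for animal, sub in df.groupby(df["animal_id"].astype(str)):
        cand = sub[sub["candidate"]]
        n_cand = len(cand)
        if n_cand == 0:
            warnings.warn(f"animal {animal} has no candidate+ cells; "
                          "omitted from candidate-composition means")
            for stat in COMPOSITION_CLASSES:
                add(animal, f"candidate_{stat}_pct", None, 0)
        else:
            comp = {
                "ha_only": (cand["ha"] & ~cand["th"]).sum(),
                "th_only": (~cand["ha"] & cand["th"]).sum(),
                "ha_and_th": (cand["ha"] & cand["th"]).sum(),
                "neither": (~cand["ha"] & ~cand["th"]).sum(),
            }
            for stat, count in comp.items():
                add(animal, f"candidate_{stat}_pct",
                    100.0 * count / n_cand, n_cand)
        for marker in ("ha", "th"):
            denom = sub[sub[marker]]
            if len(denom) == 0:
                warnings.warn(f"animal {animal} has no {marker.upper()}+ "
                              "cells; statistic flagged missing")
                add(animal, f"{marker}_pos_candidate_pct", None, 0)
            else:
                add(animal, f"{marker}_pos_candidate_pct",
                    100.0 * denom["candidate"].sum() / len(denom), len(denom))

    per_animal = pd.DataFrame(records, columns=["animal_id", "statistic",
                                                "percent", "n_denominator"])
    means = {stat: _mean_sem(vals) for stat, vals in stats.items()}
    return ColocSummary(per_animal=per_animal, means=means, n_cells=n_cells)


def write_summary(summary: ColocSummary, path,
                  candidate: str | None = None) -> None:
    """Write the cross-animal summary TSV (full precision)."""
    frame = summary.to_frame()
    if candidate is not None:
        frame.insert(0, "candidate", candidate)
    frame.to_csv(path, sep="\t", index=False)
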