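"""Regional expression density and intensity from quantified ISH volumes.

For a gene's expression grid restricted to a region mask (the VTA
analogue):

* expression density  = (# voxels with signal strictly above threshold) /
  (# voxels in the region), and
* expression intensity = mean signal over those expressing voxels
  (undefined — not zero — when no voxel expresses).

Multiple experiments for one gene are combined by unweighted arithmetic
means.  Summaries can equally be ingested from a pre-quantified
per-structure table; both pathways produce identical results on
round-tripped data.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import nrrdio
from .errors import InputError


@dataclass
class ExpressionGrid:
    """Per-voxel expression signal for one gene / one experiment.

    Axis order is (x, y, z), indices 0-based; no anatomical registration is
    implied.
    """

    gene_id: str
    experiment_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError(f"{self.gene_id}: grid values must be finite "
                             "and non-negative")


@dataclass
class RegionMask:
    """Label volume plus the id of the region of interest."""

    labels: np.ndarray
    region_id: int = 1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    def select(self, shape) -> np.ndarray:
        if self.labels.shape != tuple(shape):
            raise InputError("mask shape does not match grid shape")
        sel = self.labels == self.region_id
        if not sel.any():
            raise InputError(f"region {self.region_id} is empty")
        return sel


@dataclass
class ISHSummary:
    """Per-gene regional expression summary.

    ``expression_intensity`` is None when no voxel expresses in any
    experiment (the undefined flag; never coerced to 0).
    """

    gene_id: str
    expression_density: float
    expression_intensity: float | None
    n_voxels: int
    n_experiments: int = 1


def compute_density(grid: ExpressionGrid, mask: RegionMask,
                    threshold: float) -> float:
    """Fraction of in-region voxels expressing (value strictly > threshold)."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    region = grid.values[mask.select(grid.values.shape)]
    return float(np.count_nonzero(region > threshold) / region.size)


def compute_intensity(grid: ExpressionGrid, mask: RegionMask,
                      threshold: float) -> float | None:
    """Mean signal of expressing in-region voxels; None when none express."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    region = grid.values[mask.select(grid.values.shape)]
    expressing = region[region > threshold]
    if expressing.size == 0:
        return None
    return float(expressing.mean())


def summarize_gene(grids: Iterable[ExpressionGrid], mask: RegionMask,
                   threshold: float) -> ISHSummary:
    """Average density and intensity over a gene's experiments.

    Undefined intensities are dropped from the intensity mean; if every
    experiment is undefined the summary intensity is undefined too.
    """
    grids = list(grids)
    if not grids:
        raise InputError("summarize_gene needs at least one grid")
    gene_ids = {g.gene_id for g in grids}
    if len(gene_ids) != 1:
        raise InputError(f"grids span multiple genes: {sorted(gene_ids)}")
    densities, intensities = [], []
    n_voxels = 0
    for g in grids:
        densities.append(compute_density(g, mask, threshold))
        n_voxels = int(mask.select(g.values.shape).sum())
        inten = compute_intensity(g, mask, threshold)
        if inten is not None:
            intensities.append(inten)
    return ISHSummary(
        gene_id=gene_ids.pop(),
        expression_density=float(np.mean(densities)),
        expression_intensity=(float(np.mean(intensities))
                              if intensities else None),
        n_voxels=n_voxels,
        n_experiments=len(grids),
    )


def read_summary_table(path) -> dict[str, ISHSummary]:
    """Ingest a pre-quantified per-experiment summary TSV and average per gene.

    Columns: gene_id, experiment_id, expression_density,
    expression_intensity (empty field = undefined).  Densities outside
    [0, 1] reject the whole table with the offending rows listed.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "experiment_id", "expression_density",
                "expression_intensity"}
    if not required <= set(df.columns):
        raise InputError(f"summary table needs columns {sorted(required)}")
    bad = df[(df["expression_density"] < 0) | (df["expression_density"] > 1)
             | df["expression_density"].isna()]
    if len(bad):
        raise InputError(
            "expression_density outside [0, 1] in rows: "
            + ", ".join(str(i) for i in bad.index.tolist()))
    out: dict[str, ISHSummary] = {}
    for gene, sub in df.groupby("gene_id", sort=False):
        intens = sub["expression_intensity"].dropna()
        out[str(gene)] = ISHSummary(
            gene_id=str(gene),
            expression_density=float(sub["expression_density"].mean()),
            expression_intensity=(float(intens.mean()) if len(intens)
                                  else None),
            n_voxels=0,
            n_experiments=len(sub),
        )
    return out


def write_summary_table(summaries: dict[str, "ISHSummary"], path,
                        per_experiment: pd.DataFrame | None = None) -> None:
    """Write per-gene summaries (or a per-experiment frame) as TSV."""
    if per_experiment is not None:
        per_experiment.to_csv(path, sep="\t", index=False)
        return
    rows = [(s.gene_id, "mean", s.expression_density,
             "" if s.expression_intensity is None else s.expression_intensity)
            for s in summaries.values()]
    pd.DataFrame(rows, columns=["gene_id", "experiment_id",
                                "expression_density",
                                "expression_intensity"]).to_csv(
        path, sep="\t", index=False)


def load_grids(directory, mask_name: str = "region_mask.nrrd",
               ) -> tuple[dict[str, list[ExpressionGrid]], RegionMask]:
    """Read every gene grid NRRD in ``directory`` plus the label mask.

    Grid files are named ``<gene>__<experiment>.nrrd``.
    """
    directory = Path(directory)
    mask_arr, mask_fields = nrrdio.read_nrrd(directory / mask_name)
    mask = RegionMask(mask_arr, int(mask_fields.get("region id", 1)))
    grids: dict[str, list[ExpressionGrid]] = {}
    for path in sorted(directory.glob("*.nrrd")):
        if path.name == mask_name:
            continue
        stem = path.stem
        gene, _, exp = stem.partition("__")
        values, _ = nrrdio.read_nrrd(path)
        grids.setdefault(gene, []).append(
            ExpressionGrid(gene, exp or "exp0", values))
    return grids, mask


def summarize_directory(directory, threshold: float,
                        mask_name: str = "region_mask.nrrd",
                        ) -> dict[str, ISHSummary]:
    """Grid pathway end to end: load a directory and summarize every gene."""
    grids, mask = load_grids(directory, mask_name)
    return {gene: summarize_gene(gs, mask, threshold)
            for gene, gs in grids.items()}
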