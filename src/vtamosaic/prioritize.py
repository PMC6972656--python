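"""Candidate prioritization: population fractions, mosaicism window, funnel.

A gene's expression density divided by the density of the reference gene
(Vgat analogue, expressed by the whole GABA population) estimates the
fraction of that population expressing the gene.  Candidates are kept when
that fraction lies in the mosaicism window (5-50% by default, bounds
inclusive), show a mosaic — not absent, not widespread — regional pattern,
have a cre-driver line, and are not on the literature exclusion list.  The
:class:`FunnelLedger` records each contracting stage and enforces nesting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .errors import InputError, IntegrityError, ParameterError
from .ish import ExpressionGrid, ISHSummary, RegionMask, compute_density
from .ontology import AnnotationRecord
from .published import DEFAULT_EXCLUSIONS

logger = logging.getLogger(__name__)

WINDOW_LO = 0.05
WINDOW_HI = 0.50

#: Below this density the pattern proxy calls a gene absent from the region.
ABSENCE_FLOOR = 0.005


@dataclass(frozen=True)
class PopulationFraction:
    """Estimated fraction of the GABA population expressing a gene."""

    gene_id: str
    fraction: float
    above_reference: bool
    in_window: bool


def compute_fraction(gene: ISHSummary, reference: ISHSummary,
                     lo: float = WINDOW_LO,
                     hi: float = WINDOW_HI) -> PopulationFraction:
    """Density ratio to the reference gene, with window/overshoot flags.

    A fraction above 1 means the gene is denser than the whole-population
    reference, i.e. likely expressed in all GABA neurons or in multiple
    cell types; such genes fall outside any valid window.
    """
    if reference.expression_density <= 0:
        raise InputError("reference gene has zero expression density; it "
                         "must express in the region")
    frac = gene.expression_density / reference.expression_density
    return PopulationFraction(
        gene_id=gene.gene_id,
        fraction=frac,
        above_reference=frac > 1.0,
        in_window=lo <= frac <= hi,
    )


def apply_window(fractions: dict[str, PopulationFraction] | list[PopulationFraction],
                 lo: float = WINDOW_LO, hi: float = WINDOW_HI) -> set[str]:
    """Genes whose population fraction lies in [lo, hi] (bounds inclusive)."""
    if not 0 < lo < hi <= 1:
        raise ParameterError(f"invalid window [{lo}, {hi}]")
    if isinstance(fractions, dict):
        fractions = list(fractions.values())
    return {f.gene_id for f in fractions if lo <= f.fraction <= hi}


def filter_by_pattern(genes: set[str],
                      annotations: dict[str, AnnotationRecord]) -> set[str]:
    """Keep genes with a mosaic regional pattern.

    ``widespread`` and ``absent`` flags drop the gene; ``unknown`` flags are
    retained with a warning — pattern curation is a manual judgement and an
    uninspected gene must not be dropped silently.
    """
    kept = set()
    unknown = []
    for g in genes:
        flag = annotations[g].pattern_flag if g in annotations else "unknown"
        if flag == "mosaic":
            kept.add(g)
        elif flag == "unknown":
            unknown.append(g)
            kept.add(g)
        else:
            logger.debug("pattern filter drops %s (%s)", g, flag)
    if unknown:
        warnings.warn(f"{len(unknown)} gene(s) have no curated pattern flag "
                      "and were retained")
    return kept


def score_pattern_proxy(grid: ExpressionGrid, mask: RegionMask,
                        threshold: float, reference_density: float,
                        absence_floor: float = ABSENCE_FLOOR,
                        ) -> tuple[str, float]:
    """Automated, NON-CANONICAL stand-in for manual image inspection.

    Classifies from the density alone: below the absence floor -> absent;
    above the reference density -> widespread; otherwise mosaic.  Returns
    (class, density/reference score).  The curated flags are the default
    pathway; enable this proxy explicitly.
    """
    if reference_density <= 0:
        raise InputError("reference density must be positive")
    density = compute_density(grid, mask, threshold)
    score = density / reference_density
    if density < absence_floor:
        return "absent", score
    if density > reference_density:
        return "widespread", score
    return "mosaic", score


def filter_by_cre(genes: set[str],
                  annotations: dict[str, AnnotationRecord]) -> set[str]:
    """Keep genes with an available cre-driver mouse line."""
    return {g for g in genes
            if g in annotations and annotations[g].cre_available}


def apply_exclusions(genes: set[str],
                     exclusions: dict[str, str] | None = None) -> set[str]:
    """Remove literature-excluded genes; each removal (or no-op) is logged."""
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSIONS
    for g, reason in exclusions.items():
        if g in genes:
            logger.info("excluding %s: %s", g, reason)
        else:
            logger.debug("exclusion %s not present upstream (no-op)", g)
    return genes - set(exclusions)


@dataclass
class FunnelLedger:
    """Ordered record of the contracting filter stages.

    Each appended stage must be a subset of the previous one; a violation
    raises :class:`IntegrityError` naming the offending genes.
    """

    stages: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def append(self, name: str, genes: set[str]) -> None:
        genes = frozenset(genes)
        if self.stages:
            prev_name, prev = self.stages[-1]
            extra = genes - prev
            if extra:
                raise IntegrityError(
                    f"funnel stage {name!r} is not nested in {prev_name!r}; "
                    f"offending genes: {sorted(extra)}")
        self.stages.append((name, genes))
        logger.info("funnel stage %-20s %d genes", name, len(genes))

    @property
    def counts(self) -> list[tuple[str, int]]:
        return [(name, len(genes)) for name, genes in self.stages]

    def final(self) -> frozenset[str]:
        if not self.stages:
            raise IntegrityError("empty funnel")
        return self.stages[-1][1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(name, len(genes), ";".join(sorted(genes)))
             for name, genes in self.stages],
            columns=["stage", "count", "genes"])


def build_funnel(stage_outputs: list[tuple[str, set[str]]],
                 provenance: dict | None = None) -> FunnelLedger:
    """Assemble a ledger from (name, gene set) pairs in pipeline order."""
    ledger = FunnelLedger(provenance=dict(provenance or {}))
    for name, genes in stage_outputs:
        ledger.append(name, genes)
    return ledger
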