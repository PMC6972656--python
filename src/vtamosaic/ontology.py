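"""Ontology-category restriction of the enriched gene set.

The screen keeps only enriched genes belonging to at least one of nine
gene sub-categories (transcription factors, receptors, transporters and
related activity/binding classes) chosen because sub-group markers in
other neuronal populations fall in them.  Category membership is an input
annotation table; no ontology database is queried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .published import PANTHER_CATEGORIES

PATTERN_FLAGS = ("absent", "mosaic", "widespread", "unknown")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-gene annotation: ontology categories, cre-line availability and
    curated expression-pattern flag."""

    gene_id: str
    categories: frozenset[str]
    cre_available: bool
    pattern_flag: str = "unknown"

    def __post_init__(self) -> None:
        if self.pattern_flag not in PATTERN_FLAGS:
            raise InputError(
                f"{self.gene_id}: bad pattern flag {self.pattern_flag!r}")


@dataclass(frozen=True)
class CategorySet:
    """Ordered, duplicate-free set of category labels."""

    labels: tuple[str, ...] = PANTHER_CATEGORIES

    def __post_init__(self) -> None:
        if not self.labels:
            raise InputError("category set must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("duplicate category labels")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels


_BOOL = {"1": True, "0": False, "true": True, "false": False}


def load_annotations(path) -> dict[str, AnnotationRecord]:
    """Parse the annotation TSV (gene_id, categories ';'-joined,
    cre_available 0/1, pattern_flag)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    required = {"gene_id", "categories", "cre_available", "pattern_flag"}
    if not required <= set(df.columns):
        raise InputError(f"annotation table needs columns {sorted(required)}")
    records: dict[str, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        gid = row.gene_id
        if gid in records:
            raise InputError(f"duplicate annotation for gene {gid}")
        raw_bool = str(row.cre_available).strip().lower()
        if raw_bool not in _BOOL:
            raise InputError(f"{gid}: malformed cre_available {raw_bool!r}")
        flag = str(row.pattern_flag).strip().lower()
        if flag not in PATTERN_FLAGS:
            warnings.warn(f"{gid}: unknown pattern flag {flag!r}, "
                          "treating as 'unknown'")
            flag = "unknown"
        cats = frozenset(c.strip() for c in str(row.categories).split(";")
                         if c.strip())
        records[gid] = AnnotationRecord(gid, cats, _BOOL[raw_bool], flag)
    return records


def write_annotations(records: dict[str, AnnotationRecord], path) -> None:
    rows = [(r.gene_id, ";".join(sorted(r.categories)),
             int(r.cre_available), r.pattern_flag)
            for r in records.values()]
    pd.DataFrame(rows, columns=["gene_id", "categories", "cre_available",
                                "pattern_flag"]).to_csv(
        path, sep="\t", index=False)


def filter_by_categories(genes: set[str],
                         annotations: dict[str, AnnotationRecord],
                         categories: CategorySet | None = None) -> set[str]:
    """Genes whose annotated categories intersect the category set.

    One membership suffices.  Genes absent from the annotation table count
    as unannotated and are excluded (conservative); their number is
    reported via a warning.
    """
    categories = categories or CategorySet()
    wanted = set(categories.labels)
    unannotated = {g for g in genes if g not in annotations}
    if unannotated:
        warnings.warn(f"{len(unannotated)} gene(s) lack annotations and "
                      "were excluded from the category filter")
    return {g for g in genes
            if g in annotations and annotations[g].categories & wanted}
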