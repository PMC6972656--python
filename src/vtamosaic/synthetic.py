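"""Synthetic study inputs with planted ground truth.

Every input the prioritization pipeline consumes is generated here so the
whole funnel is testable end to end without any download: negative-binomial
IP count matrices (two groups, three biological replicates each), regional
expression grids with a label mask (the Allen-Atlas analogue), per-gene
annotation tables (ontology categories, cre availability, curated pattern
flags) and per-cell immunolabelling tables.

All randomness flows from one integer seed; each generator stage draws
from its own substream derived by a fixed offset, so adding a stage never
perturbs another stage's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nrrdio
from .coloc import CellTable
from .diffexpr import DA_IP, GABA_IP, CountMatrix
from .errors import ParameterError
from .ish import ExpressionGrid, RegionMask
from .ontology import AnnotationRecord
from .published import (DEFAULT_EXCLUSIONS, PANTHER_CATEGORIES,
                        REFERENCE_GENE)

# fixed substream offsets
_STREAM_COUNTS = 0
_STREAM_GRIDS = 1
_STREAM_CELLS = 2
_STREAM_ANNOT = 3
_STREAM_TRUTH = 4


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(offset,)))


PATTERN_CLASSES = ("absent", "mosaic", "widespread")
MARKER_CLASSES = ("gaba_marker", "da_marker", "none")


@dataclass
class GeneTruth:
    """Planted ground truth for one gene.

    ``planted_log2fc`` is GABA-IP over DA-IP on the log2 scale;
    ``mean_expression`` the expected normalized DA-IP count;
    ``dispersion`` the NB alpha in Var = mu + alpha * mu**2;
    ``expressing_fraction`` the fraction of the GABA-population voxel
    probability (values above 1 encode expression in multiple cell types).
    """

    gene_id: str
    planted_log2fc: float
    mean_expression: float
    dispersion: float
    expressing_fraction: float
    pattern_class: str
    categories: frozenset[str] = frozenset()
    cre_available: bool = False
    marker_class: str = "none"


@dataclass
class TruthTable:
    """Ordered collection of :class:`GeneTruth` rows."""

    genes: list[GeneTruth]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate gene ids in truth table")

    def validate(self, absence_floor_fraction: float = 0.025) -> None:
        for g in self.genes:
            if g.mean_expression <= 0:
                raise ParameterError(f"{g.gene_id}: mean_expression must be > 0")
            if g.dispersion < 0:
                raise ParameterError(f"{g.gene_id}: dispersion must be >= 0")
            if not 0 <= g.expressing_fraction <= 1.5:
                raise ParameterError(
                    f"{g.gene_id}: expressing_fraction outside [0, 1.5]")
            if g.pattern_class not in PATTERN_CLASSES:
                raise ParameterError(
                    f"{g.gene_id}: bad pattern class {g.pattern_class!r}")
            if g.marker_class not in MARKER_CLASSES:
                raise ParameterError(
                    f"{g.gene_id}: bad marker class {g.marker_class!r}")
            below = g.expressing_fraction < absence_floor_fraction
            if below != (g.pattern_class == "absent"):
                raise ParameterError(
                    f"{g.gene_id}: pattern_class {g.pattern_class!r} "
                    f"inconsistent with expressing_fraction "
                    f"{g.expressing_fraction}")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def __getitem__(self, gene_id: str) -> GeneTruth:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.planted_log2fc, g.mean_expression, g.dispersion,
              g.expressing_fraction, g.pattern_class,
              ";".join(sorted(g.categories)), int(g.cre_available),
              g.marker_class)
             for g in self.genes],
            columns=["gene_id", "planted_log2fc", "mean_expression",
                     "dispersion", "expressing_fraction", "pattern_class",
                     "categories", "cre_available", "marker_class"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        genes = [GeneTruth(
            gene_id=str(r.gene_id),
            planted_log2fc=float(r.planted_log2fc),
            mean_expression=float(r.mean_expression),
            dispersion=float(r.dispersion),
            expressing_fraction=float(r.expressing_fraction),
            pattern_class=str(r.pattern_class),
            categories=frozenset(c for c in str(r.categories).split(";") if c),
            cre_available=bool(int(r.cre_available)),
            marker_class=str(r.marker_class),
        ) for r in df.itertuples(index=False)]
        return cls(genes)


@dataclass
class SimulationConfig:
    """Knobs of the study emulation.

    Defaults mirror the study conditions: three biological replicates per
    IP group, modest library-size variation, a region mask of about ten
    thousand voxels, and a reference gene (the Vgat analogue) expressing in
    20% of region voxels to stand for 100% of the GABA population.
    """

    n_replicates_per_group: int = 3
    library_size_range: tuple[float, float] = (0.75, 1.25)
    grid_shape: tuple[int, int, int] = (30, 30, 15)
    mask_margin: int = 1
    reference_gene: str = REFERENCE_GENE
    reference_expressing_probability: float = 0.20
    detection_threshold: float = 1.0
    background_intensity: float = 0.5
    expressing_intensity: float = 8.0
    expressing_noise_sd: float = 0.5
    grids_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates_per_group < 2:
            raise ParameterError("need >= 2 replicates per group")
        if not (self.expressing_intensity > self.detection_threshold
                >= self.background_intensity >= 0):
            raise ParameterError(
                "need expressing_intensity > detection_threshold >= "
                "background_intensity >= 0")
        if not 0 < self.reference_expressing_probability <= 1:
            raise ParameterError(
                "reference_expressing_probability must lie in (0, 1]")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ParameterError("invalid library_size_range")
        if any(s <= 0 for s in self.grid_shape):
            raise ParameterError("grid_shape must be positive")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: float) -> np.ndarray:
    """NB(mu, Var = mu + alpha mu^2); Poisson when alpha == 0."""
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(truth: TruthTable, config: SimulationConfig,
                    ) -> CountMatrix:
    """Draw the gene x sample IP count matrix.

    DA-IP sample means are ``s_j * mean_expression``; GABA-IP means carry
    the planted fold change ``2**planted_log2fc`` on top.  Size factors
    ``s_j`` are uniform over ``library_size_range``.  Gene lengths (for
    RPKM only) are drawn once per gene from 0.5-10 kb.
    """
    truth.validate()
    rng = _rng(config.seed, _STREAM_COUNTS)
    n = config.n_replicates_per_group
    lo, hi = config.library_size_range
    s = rng.uniform(lo, hi, size=2 * n)
    sample_ids = [f"GABA_{i+1}" for i in range(n)] + \
                 [f"DA_{i+1}" for i in range(n)]
    groups = {sid: (GABA_IP if sid.startswith("GABA") else DA_IP)
              for sid in sample_ids}
    counts = np.empty((len(truth.genes), 2 * n), dtype=np.int64)
    for i, g in enumerate(truth.genes):
        mu_gaba = s[:n] * g.mean_expression * 2.0 ** g.planted_log2fc
        mu_da = s[n:] * g.mean_expression
        mu = np.concatenate([mu_gaba, mu_da])
        counts[i] = _nb_draw(rng, mu, g.dispersion)
    lengths = {g.gene_id: float(l)
               for g, l in zip(truth.genes,
                               rng.uniform(0.5, 10.0, len(truth.genes)))}
    return CountMatrix(gene_ids=truth.gene_ids, sample_ids=sample_ids,
                       counts=counts, groups=groups, gene_length_kb=lengths)


def make_region_mask(config: SimulationConfig) -> RegionMask:
    """Label volume: region id 1 inside the margin, 0 outside."""
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    m = config.mask_margin
    inner = tuple(slice(m, s - m) for s in config.grid_shape)
    labels[inner] = 1
    return RegionMask(labels, region_id=1)


def simulate_expression_grids(truth: TruthTable, config: SimulationConfig,
                              ) -> tuple[dict[str, list[ExpressionGrid]],
                                         RegionMask, dict]:
    """Draw per-gene expression volumes over a shared region mask.

    In-region voxels of gene g express independently with probability
    ``expressing_fraction_g * reference_expressing_probability`` (the
    reference gene uses the reference probability itself); expressing
    voxels carry ``expressing_intensity`` plus Gaussian noise (clipped just
    above threshold so detection is unambiguous), all other voxels uniform
    background below the detection threshold.  Probabilities that scale
    above 1 are clipped with a note in the returned provenance dict.
    """
    truth.validate()
    rng = _rng(config.seed, _STREAM_GRIDS)
    mask = make_region_mask(config)
    in_region = mask.labels == mask.region_id
    provenance: dict = {"clipped_probability": []}
    grids: dict[str, list[ExpressionGrid]] = {}
    for g in truth.genes:
        if g.gene_id == config.reference_gene:
            p = config.reference_expressing_probability
        else:
            p = g.expressing_fraction * config.reference_expressing_probability
        if p > 1.0:
            provenance["clipped_probability"].append(g.gene_id)
            p = 1.0
        gene_grids = []
        for e in range(config.grids_per_gene):
            values = rng.uniform(0.0, config.background_intensity,
                                 size=config.grid_shape)
            express = in_region & (rng.random(config.grid_shape) < p)
            signal = config.expressing_intensity + rng.normal(
                0.0, config.expressing_noise_sd, size=int(express.sum()))
            floor = config.detection_threshold * 1.001
            values[express] = np.maximum(signal, floor)
            gene_grids.append(
                ExpressionGrid(g.gene_id, f"exp{e}", values))
        grids[g.gene_id] = gene_grids
    return grids, mask, provenance


def simulate_cell_tables(p_candidate_given_gaba: float,
                         p_candidate_given_da: float,
                         cells_per_animal: int,
                         n_animals: int,
                         gaba_proportion: float,
                         seed: int,
                         double_positive_fraction: float = 0.02,
                         neither_fraction: float = 0.05,
                         p_candidate_given_neither: float = 0.0,
                         ) -> CellTable:
    """Draw a per-cell label table for one candidate marker.

    Cells are first assigned a neurochemical class: with probability
    ``neither_fraction`` neither marker; otherwise GABA (HA+) with
    probability ``gaba_proportion`` — of which a small
    ``double_positive_fraction`` are also TH+ — else dopaminergic (TH+).
    Candidate positivity then follows the class-conditional probability.
    """
    probs = [p_candidate_given_gaba, p_candidate_given_da, gaba_proportion,
             double_positive_fraction, neither_fraction,
             p_candidate_given_neither]
    if any(not 0 <= p <= 1 for p in probs):
        raise ParameterError("all probabilities must lie in [0, 1]")
    if cells_per_animal <= 0 or n_animals <= 0:
        raise ParameterError("cell and animal counts must be positive")
    rng = _rng(seed, _STREAM_CELLS)
    rows = []
    for a in range(n_animals):
        animal = f"animal_{a+1}"
        for c in range(cells_per_animal):
            if rng.random() < neither_fraction:
                ha, th = False, False
                p_cand = p_candidate_given_neither
            elif rng.random() < gaba_proportion:
                ha = True
                th = rng.random() < double_positive_fraction
                p_cand = p_candidate_given_gaba
            else:
                ha, th = False, True
                p_cand = p_candidate_given_da
            cand = rng.random() < p_cand
            rows.append((f"cell_{c+1}", animal, int(cand), int(ha), int(th)))
    frame = pd.DataFrame(rows, columns=["cell_id", "animal_id", "candidate",
                                        "ha", "th"])
    return CellTable(frame)


def simulate_annotations(truth: TruthTable, category_universe,
                         seed: int,
                         distractor_rate: float = 0.1,
                         ) -> dict[str, AnnotationRecord]:
    """Annotation records: truth categories plus random distractors.

    Every gene keeps its planted categories and independently gains each
    non-planted label from the universe with probability
    ``distractor_rate``; cre availability and the curated pattern flag are
    copied from the truth.
    """
    universe = list(category_universe)
    if not universe:
        raise ParameterError("category universe must be non-empty")
    if not 0 <= distractor_rate <= 1:
        raise ParameterError("distractor_rate must lie in [0, 1]")
    rng = _rng(seed, _STREAM_ANNOT)
    records = {}
    for g in truth.genes:
        cats = set(g.categories)
        for label in universe:
            if label not in cats and rng.random() < distractor_rate:
                cats.add(label)
        records[g.gene_id] = AnnotationRecord(
            gene_id=g.gene_id, categories=frozenset(cats),
            cre_available=g.cre_available, pattern_flag=g.pattern_class)
    return records


# ---------------------------------------------------------------------------
# Default planted truth: the study conditions in miniature.

#: Distractor ontology labels outside the nine screened categories.
OFF_TARGET_CATEGORIES = ("metabolic process", "cytoskeletal protein",
                         "immune response", "chaperone")

#: Planted in-window candidates: the seven retained genes plus the five
#: literature exclusions, all enriched, mosaic, cre-positive.  Fractions
#: span the mosaicism window.
_CANDIDATE_FRACTIONS = {
    "Cbln4": 0.10, "Gpr101": 0.15, "Rxfp3": 0.20, "Rora": 0.25,
    "Trh": 0.30, "Nrp2": 0.35, "Nos1": 0.40,
    "Gata3": 0.45, "Nts": 0.50, "En2": 0.12, "S100b": 0.18, "Sst": 0.22,
}


def default_truth_table(n_background: int = 60,
                        seed: int = 20190816) -> TruthTable:
    """The default planted truth (deterministic-recovery regime).

    Plants the IP-validation marker panels, twelve enriched in-window
    mosaic cre-positive candidates (seven retained + five exclusion-list
    genes), distractors that each exercise one funnel filter, and
    ``n_background`` null genes.  Planted enrichment effects are >= 2 on
    the log2 scale so the funnel outcome is deterministic at study-scale
    replication; dispersions are in the 0.01-0.1 range typical of
    well-powered bulk libraries.
    """
    rng = _rng(seed, _STREAM_TRUTH)
    nine = PANTHER_CATEGORIES
    genes: list[GeneTruth] = []

    def add(gid, lfc, mean, disp, ef, pattern, cats, cre, marker="none"):
        genes.append(GeneTruth(gid, lfc, mean, disp, ef, pattern,
                               frozenset(cats), cre, marker))

    # IP-validation panel: GABA-specific transcripts strongly enriched,
    # expressed by the whole GABA population (reference gene included).
    add(REFERENCE_GENE, 3.0, 800.0, 0.05, 1.0, "widespread",
        {"transporters"}, True, "gaba_marker")
    for gid, lfc in (("Gad1", 3.2), ("Gad2", 3.0), ("Gabra1", 2.4),
                     ("Pvalb", 2.2)):
        add(gid, lfc, 400.0, 0.05, 1.0, "widespread",
            {"cell communication"}, False, "gaba_marker")
    # dopamine transcripts: strongly de-enriched, widespread in the region
    # (dopamine neurons dominate the VTA).
    for gid in ("Slc6a3", "Th", "Ddc"):
        add(gid, -4.0, 1500.0, 0.05, 1.2, "widespread",
            {"transporters"}, False, "da_marker")
    # planted candidates (enriched, nine-category member, in-window,
    # mosaic, cre line available)
    for i, (gid, ef) in enumerate(_CANDIDATE_FRACTIONS.items()):
        add(gid, 2.0 + 0.1 * (i % 7), 300.0, 0.05, ef, "mosaic",
            {nine[i % len(nine)]}, True)
    # filter-specific distractors, all enriched with large effects:
    for i in range(3):   # wrong ontology category
        add(f"offcat_{i}", 2.5, 250.0, 0.05, 0.2, "mosaic",
            {OFF_TARGET_CATEGORIES[i]}, True)
    for i in range(2):   # absent from the region
        add(f"absent_{i}", 2.5, 250.0, 0.05, 0.0, "absent", {nine[i]}, True)
    for i in range(2):   # expressed above the window (not mosaic enough)
        add(f"wide_{i}", 2.5, 250.0, 0.05, 0.8, "widespread",
            {nine[i + 2]}, True)
    for i in range(2):   # denser than the reference: multiple cell types
        add(f"multi_{i}", 2.5, 250.0, 0.05, 1.2, "widespread",
            {nine[i + 4]}, True)
    for i in range(2):   # in-window density but widespread pattern on images
        add(f"patwide_{i}", 2.5, 250.0, 0.05, 0.45, "widespread",
            {nine[i + 6]}, True)
    for i in range(2):   # mosaic but no cre-driver line
        add(f"nocre_{i}", 2.5, 250.0, 0.05, 0.3, "mosaic", {nine[i]}, False)
    for i in range(5):   # de-enriched
        add(f"deenr_{i}", -2.5, 300.0, 0.05, 0.3, "mosaic", {nine[i]}, True)
    # null background
    for i in range(n_background):
        ef = float(rng.choice([0.0, 0.1, 0.3, 0.6, 1.0, 1.3]))
        pattern = ("absent" if ef < 0.025
                   else ("widespread" if ef > 0.5 else "mosaic"))
        add(f"bg_{i}", 0.0, float(rng.uniform(50, 600)),
            float(rng.uniform(0.01, 0.1)), ef, pattern,
            {str(rng.choice(nine + OFF_TARGET_CATEGORIES))},
            bool(rng.random() < 0.5))
    table = TruthTable(genes)
    table.validate()
    return table


def expected_candidates(truth: TruthTable,
                        categories=PANTHER_CATEGORIES,
                        lo: float = 0.05, hi: float = 0.50,
                        exclusions=None) -> set[str]:
    """The planted final candidate set implied by a truth table."""
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSIONS
    cats = set(categories)
    return {
        g.gene_id for g in truth.genes
        if g.planted_log2fc > 0
        and g.categories & cats
        and lo <= g.expressing_fraction <= hi
        and g.pattern_class == "mosaic"
        and g.cre_available
        and g.gene_id not in exclusions
    }


# ---------------------------------------------------------------------------
# File layout writers (one directory = one simulated study)

def write_inputs(outdir, truth: TruthTable, config: SimulationConfig,
                 cell_candidates: dict[str, float] | None = None,
                 cells_per_animal: int = 300, n_animals: int = 3,
                 distractor_rate: float = 0.0) -> None:
    """Materialize a full simulated study under ``outdir``.

    Writes counts.tsv + samples.tsv + gene_lengths.tsv, truth.tsv,
    annotations.tsv, grids/ (ASCII NRRD volumes + region_mask.nrrd) and,
    when ``cell_candidates`` maps candidate genes to their
    P(candidate | GABA), one cells_<gene>.csv per candidate.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.validate()

    m = simulate_counts(truth, config)
    counts = pd.DataFrame(m.counts, index=m.gene_ids, columns=m.sample_ids)
    counts.index.name = "gene_id"
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    pd.DataFrame(
        [(s, m.groups[s], s.split("_")[1]) for s in m.sample_ids],
        columns=["sample_id", "group", "replicate"]).to_csv(
        outdir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(m.gene_length_kb.items()),
                 columns=["gene_id", "length_kb"]).to_csv(
        outdir / "gene_lengths.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # distractor_rate defaults to 0 so the annotation table mirrors the
    # planted truth exactly (the deterministic-recovery regime); raise it
    # to exercise the category filter under annotation noise.
    records = simulate_annotations(truth, PANTHER_CATEGORIES
                                   + OFF_TARGET_CATEGORIES,
                                   seed=config.seed,
                                   distractor_rate=distractor_rate)
    from .ontology import write_annotations
    write_annotations(records, outdir / "annotations.tsv")

    grids, mask, _prov = simulate_expression_grids(truth, config)
    griddir = outdir / "grids"
    griddir.mkdir(exist_ok=True)
    nrrdio.write_nrrd(griddir / "region_mask.nrrd", mask.labels,
                      {"region id": str(mask.region_id)})
    for gene, gene_grids in grids.items():
        for g in gene_grids:
            nrrdio.write_nrrd(griddir / f"{gene}__{g.experiment_id}.nrrd",
                              g.values, {"gene": gene})

    for gene, p_gaba in (cell_candidates or {}).items():
        # stable per-gene seed offset (process-salted hash() would break
        # run-to-run determinism)
        offset = zlib.crc32(gene.encode()) % 1000
        cells = simulate_cell_tables(
            p_candidate_given_gaba=p_gaba, p_candidate_given_da=0.05,
            cells_per_animal=cells_per_animal, n_animals=n_animals,
            gaba_proportion=0.35, seed=config.seed + offset)
        from .coloc import write_cell_table
        write_cell_table(cells, outdir / f"cells_{gene}.csv")
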