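# Methods

## Scope and model

The package implements a marker-prioritization funnel for neuronal
sub-groups: cell-type differential enrichment from polysome-IP count data,
an ontology-category restriction, regional ISH expression-density
quantification normalized to a pan-population reference gene, a mosaicism
window, curated pattern / cre-line / literature-exclusion filters, and
immunolabelling co-localization statistics. The raw inputs of such a study
(RNA-seq libraries, atlas volumes, micrographs) are emulated by a
synthetic generator with planted ground truth; the pipeline itself is
agnostic to whether its inputs are simulated or real.

## Differential enrichment

Counts are modeled as negative binomial with the variance convention
Var(K) = μ + αμ². Normalization uses classical median-of-ratios size
factors: genes with any zero count are excluded from the median (the
classical definition); if no gene is positive in every sample the
estimator errs out rather than silently switching to a pseudo-reference.

Per-gene dispersion is estimated by a bias-corrected method of moments,
α̂ = (v − m̄)/(m̄² − v/n) per group, averaged over groups (the denominator
correction removes the O(1/n) bias of m̄² as an estimator of μ²).
**Moderation:** with two or three replicates per group the gene-wise
estimates are far too noisy to plug into a Wald test — measured on the
global-null simulation the purely gene-wise Wald realizes a type-I error
near 0.12 at nominal 0.05. The standard error therefore uses the
across-gene mean of the clipped gene-wise estimates (a constant
dispersion trend, i.e. full shrinkage), in the spirit of the shrinkage
all small-n RNA-seq testing relies on. This brings the realized level to
0.043–0.053 across seeds under the calibration conditions (5,000 null
genes, 3v3, μ = 100, α = 0.1). Gene-wise estimates remain available in
the output and via `dispersion_mode="genewise"`.

The test statistic is log₂FC / SE with log₂FC =
log₂((m̄_G + pc)/(m̄_D + pc)), pseudocount pc = 0.5 normalized counts
(keeps fold changes finite at zeros), SE from the NB variance of each
group mean delta-methoded to the log₂ scale, and a two-sided normal
reference. Dispersion is floored at 10⁻⁸ to prevent degenerate SEs.
Deliberately out of scope: Cook's-distance filtering, independent
filtering, fold-change shrinkage. Wald and likelihood-ratio p-values agree
at moderate effects but diverge far out in the tails — the tests compare
the two routes where asymptotic equivalence applies and compare only the
call at extreme effects.

BH adjustment delegates to statsmodels (`fdr_bh`) behind the module
surface; the test suite checks it against an O(m²) from-definition
step-up implementation. The enrichment call is inclusive at the
threshold: P-Adj ≤ α, with the fold-change sign splitting enriched from
de-enriched.

## ISH quantification

Expression density is the fraction of in-region voxels with signal
*strictly above* the detection threshold; the threshold is configuration
(real atlas pipelines bake detection into proprietary processing, so no
single value is canonical). Expression intensity is the mean signal of
expressing voxels; the denominator is read as the *count* of expressing
voxels (the summed-intensity reading would make the quantity identically
1) and intensity is *undefined* — a flag, never 0 — when nothing
expresses. Multi-experiment aggregation is the unweighted arithmetic
mean per gene, with undefined intensities dropped from the mean.
Coordinates are 0-based (x, y, z) voxel indices; no registration is
performed. Volumes travel as ASCII-encoded NRRD files via a small codec
in `vtamosaic.nrrdio`.

The population fraction is density(g)/density(reference); the reference
must express (zero reference density is an error). Fractions above 1 flag
likely multi-cell-type expression. The mosaicism window [0.05, 0.50] is
inclusive at both ends — "between 5% and 50%" is ambiguous and the
inclusive reading is surfaced as configuration. The window is applied to
density only; intensity is reported but never filtered on.

## Pattern, cre and exclusion filters

Pattern judgement (absent / mosaic / widespread) is inherently a manual,
image-inspection call, so the canonical pathway consumes curated flags;
genes with *unknown* flags are retained with a warning rather than
silently dropped. An automated proxy (`score_pattern_proxy`: density below
0.005 → absent, above the reference density → widespread, else mosaic) is
provided for fully automated runs and is marked non-canonical in every
output. Exclusions are a configurable gene → reason mapping so the
literature rationale travels with the report. Every filter is a
contraction and idempotent; the funnel ledger raises on any nesting
violation, naming the offending genes.

## Co-localization

The animal is the unit of replication (three mice in the emulated
design); SEM = sd(per-animal percentages)/√n_animals. The candidate⁺
composition classes (HA-only, TH-only, HA∧TH, neither) are exclusive and
exhaustive and sum to 100% per animal. Empty denominator classes yield
flagged-missing entries and drop that animal from the affected mean with
a warning — never a silent zero.

## Synthetic generator

All randomness flows from a single integer seed; each stage (counts,
grids, cells, annotations) draws from a substream at a fixed spawn-key
offset, so stages never perturb one another. Defaults are the study
conditions: 3 replicates per group; library-size factors uniform on
[0.75, 1.25]; a ~10,200-voxel region mask (30×30×15 grid, 1-voxel
margin); reference expressing probability 0.2; expressing voxels at
intensity 8 ± 0.5 (clipped just above the detection threshold 1.0 so
detection is unambiguous) over uniform background below 0.5; cell tables
with 35% GABA cells, a 2% HA∧TH double-positive class (the published
figure shows a small unlabeled overlap class) and a 5% neither class.
Expressing voxels are i.i.d. (salt-and-pepper); real ISH texture is
spatially clustered, so passing recovery tests demonstrate estimator
correctness, not robustness to spatial autocorrelation. Likewise the
generator plants clean class-conditional probabilities; antibody
sensitivity, section-to-section variation and image-segmentation error
are not modeled.

The default truth table plants the IP-validation marker panels, twelve
enriched in-window mosaic cre-positive candidates (seven retained plus
the five literature exclusions), one distractor family per funnel filter,
and 60 null background genes — 98 genes in all. Planted candidate effects
are ≥ 2 log₂ units so that recovery is deterministic at study-scale
replication (the deterministic regime); the power/bias regression anchor
uses balanced ±1.5 effects because the emulated study's differential
expression was itself nearly symmetric, and median-of-ratios factors are
biased under strongly asymmetric differential expression (a known
property of the estimator, not an implementation artifact). In the
deterministic regime the materialized annotation table carries the
planted categories without distractors; the distractor rate is exposed
for stress-testing the category filter.

## Problem sizes and determinism

The shipped simulations are sized for interactive runs: 98-gene studies
for end-to-end recovery, 5,000 genes for null calibration, 100 random
instances per oracle-equivalence check, ~10⁴-voxel masks for fraction
recovery (3-binomial-SE bands). Reruns at a fixed seed are byte-identical,
including written reports (no timestamps in outputs). The worst-case
fraction-recovery z-statistic is a maximum over ~90 simultaneous checks
and occasionally exceeds 3 at unlucky seeds; the fixed-seed assertions
document the seed they hold at.

## Known limitations

- The NB test is a simplified estimator, not a DESeq2 re-implementation;
  numerical parity with DESeq2 output is not claimed.
- The published funnel counts (3,364 → 690 → 255 → 61 → 12 → 7) depend on
  the original RNA-seq libraries and atlas archive and are out of scope;
  the package reproduces the funnel's arithmetic and shape, not those
  counts.
- Printed co-localization percentages (38%, 46%, 43%, 52%) rest on
  unpublished per-category cell counts; the package computes the same
  statistics from supplied or simulated tables instead.
- Sub-region spatial structure (e.g. restriction to individual VTA
  nuclei) is not modeled; the label mask supports multiple region ids if
  such structure is supplied.
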