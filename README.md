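# vtamosaic

Tools for discovering **mosaically expressed molecular markers of neuronal
sub-groups**, modeled on a screen for markers of GABA neuron sub-groups in
the mouse ventral tegmental area (VTA). GABA neurons there play diverse
roles in reward and aversion, but genetic access to their sub-groups
requires marker genes expressed in *some* — not all, not none — of the
population. The package implements the full prioritization funnel as a
tested, reusable pipeline, together with a synthetic-data generator that
emulates every raw input (cell-type-tagged polysome-IP RNA-seq counts,
Allen-Atlas-style ISH expression volumes, annotation tables and per-cell
immunolabelling counts) with planted ground truth.

## The method

1. **Differential enrichment.** Gene counts from GABA-IP vs dopamine-IP
   polysome immunoprecipitates (RiboTag; *n* = 3 biological replicates per
   group) are normalized with median-of-ratios size factors and tested per
   gene under a negative-binomial model, Var(K) = μ + αμ². The Wald
   statistic is log₂FC/SE with a moderated (across-gene pooled,
   bias-corrected method-of-moments) dispersion; p-values are BH-adjusted
   and genes with P-Adj ≤ 0.05 and log₂FC > 0 are called enriched.
2. **Ontology restriction.** Enriched genes are kept only if annotated to
   at least one of nine screened gene sub-categories (transcription
   factors, cell communication, receptors, receptor activity, receptor
   binding, transporters, transporter activity, signal transducer
   activity, signalling molecules).
3. **Mosaicism window.** From quantified ISH volumes, expression density =
   (# expressing voxels)/(# region voxels) and expression intensity = mean
   signal of expressing voxels. The density of a pan-population reference
   gene (*Vgat*, expressed by all GABA neurons) defines 100% of the
   population; each gene's **population fraction** is density(g) /
   density(*Vgat*). Genes expressed in 5–50% of the population (bounds
   inclusive) are retained; fractions above 1 indicate multi-cell-type
   expression.
4. **Pattern, cre, exclusions.** Genes without regional expression or with
   widespread patterns are discarded (curated flags; an automated density
   proxy exists but is marked non-canonical), then genes lacking
   cre-driver mouse lines, then literature exclusions (e.g. pan-GABA
   genes, dopamine-expressed genes, glial markers).
5. **Co-localization.** For validated candidates, per-cell counts of
   candidate/HA/TH positivity give the composition of candidate⁺ cells
   (HA-only / TH-only / both / neither, summing to 100% per animal) and
   the fraction of HA⁺ cells expressing the candidate, as mean ± SEM
   across animals.

Every filter is a contraction and the stage ledger enforces funnel
nesting. The published worked examples ship in `vtamosaic.published`: the
six-gene validated candidate table (enrichment gate) and the
twelve-to-seven exclusion arithmetic.

## Worked example

The numbered scripts under `analysis/` run the study in miniature
(simulate → enrich → quantify → prioritize → co-localize):

```sh
python analysis/01_simulate_study.py 1
python analysis/04_prioritize_candidates.py 1
```

prints, with the default planted truth (98 genes, seed 1):

```
funnel:
  tested                  98
  enriched                30
  ontology_category       27
  density_window          16
  mosaic_pattern          14
  cre_line                12
  candidates               7

candidates:
  Nrp2       log2FC=+2.63  P-Adj=1e-18  fraction=33.1%
  ...
  Gpr101     log2FC=+1.56  P-Adj=2e-07  fraction=15.0%

recovery of planted candidate set: exact
```

The funnel counts are the surviving gene sets after each filter; the
fraction column is the estimated share of the GABA population expressing
each candidate (all within the 5–50% window); "exact" means the final
stage equals the planted candidate set with no false positives or
negatives. Tables land under `results/`, bulky simulated volumes under
`scratch/`.

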