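"""Differential enrichment of GABA-IP vs DA-IP counts.

Loads the simulated count matrix, runs median-of-ratios normalization, the
moderated NB Wald test and BH adjustment, validates the IP marker panel,
and writes the per-gene results plus the z-scored RPKM matrix.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

import pandas as pd

from vtamosaic.diffexpr import (CountMatrix, compute_rpkm_zscore,
                                partition_calls, run_de,
                                validate_marker_panel)
from vtamosaic.published import DA_MARKERS, GABA_MARKERS

ALPHA = 0.05


def main() -> None:
    if not STUDY.exists():
        sys.exit("run analysis/01_simulate_study.py first")
    lengths = pd.read_csv(STUDY / "gene_lengths.tsv", sep="\t")
    m = CountMatrix.from_tsv(
        STUDY / "counts.tsv", STUDY / "samples.tsv",
        dict(zip(lengths["gene_id"], lengths["length_kb"])))

    res = run_de(m, alpha=ALPHA)
    RESULTS.mkdir(exist_ok=True)
    res.to_csv(RESULTS / "de_results.tsv", sep="\t", index=False)
    compute_rpkm_zscore(m).to_csv(RESULTS / "rpkm_zscore.tsv", sep="\t")

    parts = partition_calls(res)
    print(f"tested {len(res)} genes at alpha={ALPHA}:")
    for call, genes in parts.items():
        print(f"  {call:<16} {len(genes)}")

    panel = validate_marker_panel(res, GABA_MARKERS, DA_MARKERS)
    status = "PASS" if panel.passed else f"FAIL ({panel.failures()})"
    print(f"IP marker panel (GABA enriched, dopamine not): {status}")
    print(f"wrote {RESULTS / 'de_results.tsv'}")


if __name__ == "__main__":
    main()
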