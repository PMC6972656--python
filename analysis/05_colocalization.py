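"""Candidate co-localization with HA (GABA) and TH (dopamine) labels.

Summarizes the per-cell tables for each candidate with simulated
immunolabelling: composition of candidate+ cells and the fraction of HA+
(and TH+) cells expressing the candidate, as mean +/- SEM across animals.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

from vtamosaic.coloc import (read_cell_table, summarize_colocalization,
                             write_summary)


def main() -> None:
    tables = sorted(STUDY.glob("cells_*.csv"))
    if not tables:
        sys.exit("run analysis/01_simulate_study.py first")
    RESULTS.mkdir(exist_ok=True)
    for path in tables:
        gene = path.stem.removeprefix("cells_")
        cells = read_cell_table(path)
        summary = summarize_colocalization(cells)
        write_summary(summary, RESULTS / f"coloc_{gene}.tsv",
                      candidate=gene)
        print(f"{gene} ({len(cells.frame)} cells, "
              f"{len(cells.animals)} animals):")
        for stat, (mean, sem, n) in summary.means.items():
            print(f"  {stat:<28} {mean:5.1f}% +/- {sem:.1f} (n={n})")
    print(f"wrote per-candidate summaries under {RESULTS}")


if __name__ == "__main__":
    main()
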