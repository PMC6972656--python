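"""Materialize the synthetic study: IP counts, expression grids, annotations
and cell tables with planted ground truth.

Writes the study inputs under scratch/study/ (volumes are bulky) and the
planted truth table under results/.  Everything downstream (02-04) reads
from that directory.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

from vtamosaic.synthetic import (SimulationConfig, default_truth_table,
                                 expected_candidates, write_inputs)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    truth = default_truth_table()
    cfg = SimulationConfig(seed=SEED)
    write_inputs(STUDY, truth, cfg,
                 cell_candidates={"Cbln4": 0.38, "Gpr101": 0.46})
    RESULTS.mkdir(exist_ok=True)
    truth.to_frame().to_csv(RESULTS / "planted_truth.tsv", sep="\t",
                            index=False)

    n_enriched = sum(g.planted_log2fc > 0 for g in truth.genes)
    planted = expected_candidates(truth)
    print(f"simulated study written to {STUDY}")
    print(f"  genes: {len(truth.genes)}  (planted enriched: {n_enriched})")
    print(f"  replicates per IP group: {cfg.n_replicates_per_group}")
    print(f"  region mask voxels: ~10^4, reference expressing probability "
          f"{cfg.reference_expressing_probability}")
    print(f"  planted final candidates ({len(planted)}): "
          f"{', '.join(sorted(planted))}")
    print(f"  seed: {SEED}")


if __name__ == "__main__":
    main()
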