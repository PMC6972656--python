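"""Published reference values for the VTA GABA-neuron marker screen.

Small tables printed in the original study report: the validated candidate
genes with their GABA-IP vs DA-IP enrichment statistics, the marker panels
used to validate the immunoprecipitation, the nine PANTHER ontology
sub-categories, and the literature-based exclusion list.  These are inputs
to worked examples and default configuration, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

#: Validated candidate genes: symbol -> (gene name, function note,
#: log2 fold change GABA-IP vs DA-IP, BH-adjusted p, cre-driver reference).
CANDIDATE_TABLE: pd.DataFrame = pd.DataFrame(
    [
        ("Gpr101", "G protein-coupled receptor 101",
         "Orphan G protein-coupled receptor", 1.24, 4.25e-06,
         "Reinius et al., (2015)"),
        ("Cbln4", "Cerebellin 4 precursor",
         "Small secreted protein", 1.28, 1.42e-05, "MMRRC"),
        ("Rxfp3", "Relaxin/insulin-like family peptide receptor 3",
         "G protein-coupled receptor for relaxin-3", 1.71, 4.59e-05, "MMRRC"),
        ("Rora", "RAR-related orphan receptor A",
         "Nuclear hormone receptor", 1.10, 4.95e-04, "Wu et al., (2010)"),
        ("Trh", "Thyrotropin-releasing hormone",
         "Hormone", 1.50, 1.67e-03, "Sugrue et al., (2010)"),
        ("Nrp2", "Neuropilin 2",
         "Transmembrane receptor for semaphorin 3C", 0.42, 4.10e-02,
         "Wiszniak et al., (2015)"),
    ],
    columns=["symbol", "gene_name", "function", "log2fc", "p_adj",
             "cre_driver"],
)

#: The twelve genes surviving the funnel through the cre-line step
#: (enriched, mosaic in the VTA, cre-driver line available).
TWELVE_CRE_CANDIDATES: frozenset[str] = frozenset({
    "Cbln4", "Gpr101", "Rxfp3", "Rora", "Trh", "Nrp2", "Nos1",
    "Gata3", "Nts", "En2", "S100b", "Sst",
})

#: Literature-based exclusions applied after the cre-line step, with the
#: reason each was set aside.
DEFAULT_EXCLUSIONS: dict[str, str] = {
    "Gata3": "expressed in all GABA neurons of the midbrain, not a sub-group marker",
    "Nts": "evidence of expression in midbrain dopamine neurons",
    "En2": "evidence of expression in midbrain dopamine neurons",
    "S100b": "glial marker; likely glial contamination or false positive",
    "Sst": "immunolabelling fails to reveal SST+ cells in the VTA",
}

#: Seven-gene candidate list after exclusions (includes Nos1, whose known
#: restriction to a GABA sub-population validates the funnel).
SEVEN_CANDIDATES: frozenset[str] = frozenset({
    "Cbln4", "Gpr101", "Rxfp3", "Rora", "Trh", "Nrp2", "Nos1",
})

#: GABA neuron-specific transcripts expected enriched in GABA-IP samples.
GABA_MARKERS: tuple[str, ...] = ("Slc32a1", "Gad1", "Gad2", "Gabra1", "Pvalb")

#: Dopamine neuron-related transcripts expected NOT enriched in GABA-IP.
DA_MARKERS: tuple[str, ...] = ("Slc6a3", "Th", "Ddc")

#: The nine PANTHER gene sub-categories used to restrict the enriched set.
PANTHER_CATEGORIES: tuple[str, ...] = (
    "transcription factors",
    "cell communication",
    "receptors",
    "receptor activity",
    "receptor binding",
    "transporters",
    "transporter activity",
    "signal transducer activity",
    "signalling molecules",
)

#: Reference gene whose expression density stands for 100% of the GABA
#: population (vesicular GABA transporter).
REFERENCE_GENE: str = "Slc32a1"
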