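"""Differential enrichment of GABA-IP vs dopamine-IP count data.

Calls genes enriched in the GABA-immunoprecipitated polysome samples
relative to the dopamine-IP samples using a negative-binomial Wald test on
median-of-ratios-normalized counts, with Benjamini-Hochberg control of the
false discovery rate.  The model follows the DESeq2 convention
``Var(K) = mu + alpha * mu**2``; dispersion is estimated per gene by a
bias-corrected method of moments and, because the design here is small
(three biological replicates per group), moderated by pooling across genes
before entering the Wald standard error.  This is a deliberately simple
estimator: no Cook's distance filtering, no independent filtering, no
fold-change shrinkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError

GABA_IP = "GABA_IP"
DA_IP = "DA_IP"

#: Lower bound on the dispersion used in standard errors.
DISPERSION_FLOOR = 1e-8

#: Pseudocount (in normalized-count units) stabilizing log fold changes.
PSEUDOCOUNT = 0.5

CALL_ENRICHED = "enriched"
CALL_DE_ENRICHED = "de_enriched"
CALL_NS = "not_significant"


@dataclass
class CountMatrix:
    """Gene x sample count matrix with IP-group labels.

    ``counts`` is genes x samples, non-negative integers.  ``groups`` maps
    each sample id to ``GABA_IP`` or ``DA_IP``.  ``gene_length_kb`` is only
    needed for RPKM and may be omitted otherwise.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: dict[str, str]
    gene_length_kb: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError("counts shape does not match gene/sample ids")
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("gene_ids must be unique")
        got = {self.groups[s] for s in self.sample_ids}
        if got - {GABA_IP, DA_IP}:
            raise InputError(f"unknown group labels: {got - {GABA_IP, DA_IP}}")
        if got != {GABA_IP, DA_IP}:
            raise InputError("both IP groups must be present")

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        return np.array([j for j, s in enumerate(self.sample_ids)
                         if self.groups[s] == group], dtype=int)

    @classmethod
    def from_tsv(cls, counts_path, samples_path,
                 lengths: dict[str, float] | None = None) -> "CountMatrix":
        """Load counts + sample sheet from the tab-separated interchange format."""
        counts = pd.read_csv(counts_path, sep="\t", comment="#",
                             index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t", comment="#")
        if not {"sample_id", "group"} <= set(sheet.columns):
            raise InputError("sample sheet needs sample_id and group columns")
        groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"]))
        missing = [s for s in counts.columns if s not in groups]
        if missing:
            raise InputError(f"samples missing from sheet: {missing}")
        mat = counts.to_numpy()
        if not np.allclose(mat, np.round(mat)):
            raise InputError("counts must be integers")
        return cls(
            gene_ids=[str(g) for g in counts.index],
            sample_ids=[str(c) for c in counts.columns],
            counts=mat.astype(np.int64),
            groups=groups,
            gene_length_kb=dict(lengths or {}),
        )


def estimate_size_factors(m: CountMatrix) -> dict[str, float]:
    """Median-of-ratios size factors.

    Each sample's factor is the median, over genes with strictly positive
    counts in every sample, of that gene's count divided by its geometric
    mean across samples.
    """
    k = m.counts.astype(float)
    allpos = np.all(k > 0, axis=1)
    if not np.any(allpos):
        raise InputError(
            "no gene has positive counts in every sample; median-of-ratios "
            "is undefined (a pseudo-reference fallback is not applied "
            "silently)")
    kp = k[allpos]
    log_geomean = np.mean(np.log(kp), axis=1, keepdims=True)
    ratios = np.exp(np.log(kp) - log_geomean)
    factors = np.median(ratios, axis=0)
    return dict(zip(m.sample_ids, factors.tolist()))


def _mom_dispersion(group_values: list[np.ndarray]) -> np.ndarray:
    """Per-gene bias-corrected method-of-moments dispersion.

    For each group the moment estimator is (v - m) / (m^2 - v/n); the
    denominator correction removes the O(1/n) bias of m^2 as an estimate of
    mu^2.  Group estimates are averaged; non-finite values (all-zero genes)
    give 0.
    """
    ests = []
    for g in group_values:
        n = g.shape[1]
        mean = g.mean(axis=1)
        var = g.var(axis=1, ddof=1)
        denom = mean**2 - var / n
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mean) / np.where(denom > 0, denom, np.nan)
        ests.append(a)
    a_gene = np.nanmean(np.stack(ests), axis=0)
    return np.where(np.isfinite(a_gene), a_gene, 0.0)


def fit_nb_test(m: CountMatrix, factors: dict[str, float],
                pseudocount: float = PSEUDOCOUNT,
                dispersion_mode: str = "moderated") -> pd.DataFrame:
    """Per-gene NB Wald test of GABA-IP vs DA-IP enrichment.

    Returns a frame with gene_id, base_mean, log2fc (GABA over DA), se,
    dispersion, p_raw; ``p_adj`` is left unset for :func:`adjust_bh`.

    ``dispersion_mode='moderated'`` (default) uses the across-gene mean of
    the clipped gene-wise estimates in the Wald standard error — with two or
    three replicates per group the gene-wise estimates are far too noisy to
    test against directly.  ``'genewise'`` uses each gene's own estimate.
    """
    fac = np.array([factors[s] for s in m.sample_ids], dtype=float)
    if np.any(fac <= 0):
        raise ParameterError("size factors must be positive")
    if dispersion_mode not in ("moderated", "genewise"):
        raise ParameterError(f"unknown dispersion_mode {dispersion_mode!r}")
    cols_g = m.group_columns(GABA_IP)
    cols_d = m.group_columns(DA_IP)
    if len(cols_g) < 2 or len(cols_d) < 2:
        raise ParameterError("need >=2 samples per group")

    q = m.counts / fac  # normalized counts
    qg, qd = q[:, cols_g], q[:, cols_d]
    n_g, n_d = len(cols_g), len(cols_d)
    mean_g, mean_d = qg.mean(axis=1), qd.mean(axis=1)
    base_mean = q.mean(axis=1)

    a_gene = np.clip(_mom_dispersion([qg, qd]), 0.0, None)
    if dispersion_mode == "moderated":
        a_used = np.full_like(a_gene, max(float(a_gene.mean()),
                                          DISPERSION_FLOOR))
    else:
        a_used = np.clip(a_gene, DISPERSION_FLOOR, None)

    log2fc = np.log2((mean_g + pseudocount) / (mean_d + pseudocount))
    # NB variance of each group mean of normalized counts, delta method to
    # the log2 scale (pseudocount kept in the denominator for stability).
    var_mean_g = (mean_g + a_used * mean_g**2) / n_g
    var_mean_d = (mean_d + a_used * mean_d**2) / n_d
    se = np.sqrt(var_mean_g / (mean_g + pseudocount)**2
                 + var_mean_d / (mean_d + pseudocount)**2) / np.log(2)
    se = np.maximum(se, 1e-12)
    z = log2fc / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    # a gene silent in one group has its fold change held finite purely by
    # the pseudocount; flag it
    zero_group = (mean_g == 0) | (mean_d == 0)

    return pd.DataFrame({
        "gene_id": m.gene_ids,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "dispersion": a_gene,
        "p_raw": p_raw,
        "p_adj": np.nan,
        "zero_group": zero_group,
    })


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enriched(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Partition genes into enriched / de-enriched / not significant.

    A gene is enriched when p_adj <= alpha (inclusive) and log2fc > 0,
    de-enriched when p_adj <= alpha and log2fc < 0.  Fills ``p_adj`` from
    ``p_raw`` if unset and appends a ``call`` column.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    out = results.copy()
    if out["p_adj"].isna().any():
        out["p_adj"] = adjust_bh(out["p_raw"].to_numpy())
    sig = out["p_adj"] <= alpha
    out["call"] = np.where(sig & (out["log2fc"] > 0), CALL_ENRICHED,
                           np.where(sig & (out["log2fc"] < 0),
                                    CALL_DE_ENRICHED, CALL_NS))
    return out


def partition_calls(results: pd.DataFrame) -> dict[str, set[str]]:
    """The three call classes as gene-id sets."""
    return {
        call: set(results.loc[results["call"] == call, "gene_id"])
        for call in (CALL_ENRICHED, CALL_DE_ENRICHED, CALL_NS)
    }


def compute_rpkm_zscore(m: CountMatrix) -> pd.DataFrame:
    """Per-gene z-scored RPKM matrix (genes x samples).

    RPKM = count / (gene length in kb * mapped reads in millions); each
    gene row is then standardized to mean 0, sd 1 (constant rows map to 0).
    Genes without a length are dropped with a warning.
    """
    totals = m.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise InputError("every sample needs a positive read total")
    have_len = [g in m.gene_length_kb for g in m.gene_ids]
    if not all(have_len):
        dropped = [g for g, ok in zip(m.gene_ids, have_len) if not ok]
        warnings.warn(f"dropping {len(dropped)} gene(s) without length: "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    keep = np.array(have_len)
    genes = [g for g in m.gene_ids if g in m.gene_length_kb]
    lengths = np.array([m.gene_length_kb[g] for g in genes])
    if np.any(lengths <= 0):
        raise InputError("gene lengths must be positive")
    rpkm = m.counts[keep] / (lengths[:, None] * (totals[None, :] / 1e6))
    mu = rpkm.mean(axis=1, keepdims=True)
    sd = rpkm.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (rpkm - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=genes, columns=m.sample_ids)


@dataclass
class MarkerPanelReport:
    """Outcome of the IP-validation marker panel check."""

    gaba_status: dict[str, bool]
    da_status: dict[str, bool]
    missing: list[str]
    passed: bool

    def failures(self) -> list[str]:
        bad = [g for g, ok in self.gaba_status.items() if not ok]
        bad += [g for g, ok in self.da_status.items() if not ok]
        return bad + list(self.missing)


def validate_marker_panel(results: pd.DataFrame,
                          gaba_markers,
                          da_markers) -> MarkerPanelReport:
    """Check that GABA-specific markers are enriched and DA markers are not.

    The panel passes only when every GABA marker is called enriched and no
    dopamine marker is; markers absent from the results fail the panel and
    are listed as missing.
    """
    if "call" not in results.columns:
        raise InputError("results must carry calls; run call_enriched first")
    calls = dict(zip(results["gene_id"], results["call"]))
    missing = [g for g in list(gaba_markers) + list(da_markers)
               if g not in calls]
    gaba_status = {g: calls.get(g) == CALL_ENRICHED
                   for g in gaba_markers if g in calls}
    da_status = {g: calls.get(g) != CALL_ENRICHED
                 for g in da_markers if g in calls}
    passed = (not missing and all(gaba_status.values())
              and all(da_status.values()))
    return MarkerPanelReport(gaba_status, da_status, missing, passed)


def run_de(m: CountMatrix, alpha: float = 0.05,
           dispersion_mode: str = "moderated") -> pd.DataFrame:
    """Convenience: size factors -> NB Wald -> BH -> calls."""
    factors = estimate_size_factors(m)
    res = fit_nb_test(m, factors, dispersion_mode=dispersion_mode)
    res["p_adj"] = adjust_bh(res["p_raw"].to_numpy())
    return call_enriched(res, alpha=alpha)
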