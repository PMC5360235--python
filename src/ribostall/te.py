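"""Translational efficiency (TE) and the ribo-vs-mRNA change decomposition.

TE is a gene's footprint density divided by its mRNA abundance.  A
compound acting purely at the translation step changes footprint counts
while leaving mRNA counts alone, so its targets appear as TE outliers
and, in the paired Z-score plane (ribo change vs mRNA change), spread
solely along the ribo axis.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .zscore import DEFAULT_BIN_SIZE, local_zscore


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors for a gene x sample count matrix.

    Each sample's factor is the median across genes of the ratio to the
    per-gene geometric mean, computed over genes with all-positive
    counts.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.sum() == 0:
        raise ValueError("no gene has positive counts in every sample")
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns)


def _normalized_condition_means(counts: pd.DataFrame, design: pd.DataFrame
                                ) -> pd.DataFrame:
    sf = median_of_ratios_size_factors(counts)
    norm = counts / sf
    out = {}
    for cond, rows in design.groupby("condition"):
        out[cond] = norm[rows.index].mean(axis=1)
    return pd.DataFrame(out)


def translational_efficiency(
    ribo_counts: pd.DataFrame,
    mrna_counts: pd.DataFrame,
    ribo_design: pd.DataFrame,
    mrna_design: pd.DataFrame,
    exclude: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene TE per condition and its treatment/vehicle log2 change.

    Counts are whole-CDS, normalized median-of-ratios within each assay.
    TE(condition) = normalized ribo mean / normalized mRNA mean.  Genes
    with a zero mRNA mean in any condition have no defined TE and are
    excluded (``te_defined`` False) rather than imputed; ``exclude``
    removes genes known to be unquantifiable in the mRNA assay (e.g.
    non-poly-adenylated histone transcripts, which poly-A selection
    underrepresents).
    """
    genes = ribo_counts.index.intersection(mrna_counts.index)
    ribo = _normalized_condition_means(ribo_counts.loc[genes], ribo_design)
    mrna = _normalized_condition_means(mrna_counts.loc[genes], mrna_design)
    out = pd.DataFrame(index=genes)
    defined = (mrna > 0).all(axis=1) & (ribo > 0).all(axis=1)
    if exclude is not None:
        defined &= ~out.index.isin(list(exclude))
    for cond in ribo.columns:
        te = ribo[cond] / mrna[cond]
        out[f"te_{cond}"] = te.where(defined)
    out["log2_dte"] = np.log2(out["te_treatment"] / out["te_vehicle"])
    out["expression"] = ribo_counts.loc[genes].sum(axis=1)
    out["te_defined"] = defined
    return out


def dte_zscores(te_table: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE,
                z_flag: float = 3.0) -> pd.DataFrame:
    """Local Z-scores of log2 TE changes; outliers flagged at |Z| > z_flag."""
    out = te_table.copy()
    defined = out["te_defined"] & out["log2_dte"].notna()
    z = local_zscore(out.loc[defined, "log2_dte"],
                     out.loc[defined, "expression"], bin_size)
    out["z_dte"] = z.reindex(out.index)
    out["te_outlier"] = out["z_dte"].abs() > z_flag
    return out


def assay_change_decomposition(
    ribo_counts: pd.DataFrame,
    mrna_counts: pd.DataFrame,
    ribo_design: pd.DataFrame,
    mrna_design: pd.DataFrame,
    bin_size: int = DEFAULT_BIN_SIZE,
    z_flag: float = 3.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Paired Z-scores of per-gene ribo-seq and mRNA-seq count changes.

    For each assay, the log2 change of normalized treatment vs vehicle
    mean counts is Z-scored against genes of similar expression.
    ``translation_only`` marks genes whose footprint change is an outlier
    while their mRNA change is not (|z_ribo| >= z_flag, |z_mrna| <
    z_flag) — the signature of an effect at the translation step.
    """
    genes = ribo_counts.index.intersection(mrna_counts.index)
    out = pd.DataFrame(index=genes)
    for assay, counts, design in (("ribo", ribo_counts, ribo_design),
                                  ("mrna", mrna_counts, mrna_design)):
        means = _normalized_condition_means(counts.loc[genes], design)
        change = np.log2((means["treatment"] + pseudocount)
                         / (means["vehicle"] + pseudocount))
        expr = counts.loc[genes].sum(axis=1)
        out[f"log2_change_{assay}"] = change
        out[f"z_{assay}_change"] = local_zscore(change, expr, bin_size)
    out["translation_only"] = ((out["z_ribo_change"].abs() >= z_flag)
                               & (out["z_mrna_change"].abs() < z_flag))
    out["both_assays"] = ((out["z_ribo_change"].abs() >= z_flag)
                          & (out["z_mrna_change"].abs() >= z_flag))
    return out
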