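"""Stall detection: CFR curves, D_max, downstream differential expression.

The central statistic works on cumulative fractional read (CFR) curves:
at each codon, the fraction of a transcript's footprints mapping at or 5'
of that codon.  A drug-induced elongation stall makes the treatment curve
rise faster 5' of the stall and level off 3' of it; the maximum
treatment-minus-vehicle divergence (D_max) and the codon where it occurs
(D_max position, which falls 3' of the last stall) locate the effect.
D_max values are standardized against genes of similar read depth
(expression-binned Z-scores), and genes passing the Z >= 2 gate have
their footprints 3' of the D_max position submitted to a negative-
binomial differential expression test; everything else is tested 3' of
codon 50.  A gene is called sensitive when the Z-gate, an FDR < 0.1 and a
negative fold change all hold.

Center-of-density analysis is the complementary statistic: the
count-weighted mean read position per CDS, whose treatment-vs-vehicle
shift is Z-scored the same way; variants omitting the first 50/100/150
codons localize stalls to the 5' end of the CDS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ingest import CodonCounts
from .zscore import DEFAULT_BIN_SIZE, local_zscore

logger = logging.getLogger(__name__)

DEFAULT_Z_MIN = 2.0
DEFAULT_FDR_MAX = 0.1
DEFAULT_BOUNDARY_CODON = 50
DEFAULT_MIN_READS = 64
DEFAULT_COD_Z_MIN = 3.0


# ---------------------------------------------------------------------------
# CFR and D_max


def cfr_curve(codon_counts: np.ndarray) -> np.ndarray:
    """Cumulative fraction of footprints at or 5' of each codon.

    The curve is nondecreasing and ends at 1; transcripts with zero total
    reads have no defined curve (callers exclude and tally them).
    """
    total = codon_counts.sum()
    if total <= 0:
        raise ValueError("CFR undefined for a transcript with zero reads")
    return np.cumsum(codon_counts) / total


def dmax(cfr_treatment: np.ndarray, cfr_vehicle: np.ndarray
         ) -> Tuple[float, int]:
    """Maximum signed CFR divergence and its codon.

    Returns ``(dmax, dmax_codon)``: the signed value of
    (treatment - vehicle) at the codon where the divergence magnitude is
    maximal.  Stalls shift treatment reads 5' and give positive D_max;
    swapping the conditions negates it.  The codon index is 1-based and,
    on ties, the 3'-most codon attaining the maximum — the position's
    only role is a 5' boundary for downstream counting, and the most-3'
    choice excludes the whole stall region.
    """
    if cfr_treatment.shape != cfr_vehicle.shape:
        raise ValueError("CFR curves span different codon ranges")
    diff = cfr_treatment - cfr_vehicle
    mag = np.abs(diff)
    m = mag.max()
    # last index attaining the maximum magnitude (3'-most)
    codon = int(len(diff) - 1 - np.argmax(mag[::-1] >= m)) + 1
    return float(diff[codon - 1]), codon


def pooled_codon_counts(codon_maps: Sequence[CodonCounts]) -> CodonCounts:
    """Sum replicate codon maps gene-wise."""
    out: Dict[str, np.ndarray] = {}
    for cm in codon_maps:
        for tid, vec in cm.items():
            if tid in out:
                out[tid] = out[tid] + vec
            else:
                out[tid] = vec.copy()
    return out


def dmax_table(
    treatment_maps: Sequence[CodonCounts],
    vehicle_maps: Sequence[CodonCounts],
    min_reads: int = DEFAULT_MIN_READS,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Per-gene D_max from replicate-pooled counts, with local Z-scores.

    Genes with fewer than ``min_reads`` pooled CDS reads in either
    condition are excluded (their CFR is dominated by single reads) and
    do not appear in the output.  ``expression`` is the pooled raw read
    count across both conditions, the axis used for binning.
    """
    pooled_t = pooled_codon_counts(treatment_maps)
    pooled_v = pooled_codon_counts(vehicle_maps)
    rows = []
    for tid in sorted(set(pooled_t) & set(pooled_v)):
        ct, cv = pooled_t[tid], pooled_v[tid]
        nt_, nv = int(ct.sum()), int(cv.sum())
        if nt_ < min_reads or nv < min_reads:
            continue
        d, codon = dmax(cfr_curve(ct), cfr_curve(cv))
        rows.append((tid, d, codon, nt_ + nv))
    df = pd.DataFrame(rows, columns=["gene_id", "dmax", "dmax_codon",
                                     "expression"]).set_index("gene_id")
    if len(df):
        df["zscore"] = local_zscore(df["dmax"], df["expression"], bin_size)
    else:
        df["zscore"] = pd.Series(dtype=float)
    return df


def null_dmax(
    vehicle_rep_a: Sequence[CodonCounts],
    vehicle_rep_b: Sequence[CodonCounts],
    min_reads: int = DEFAULT_MIN_READS,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """D_max computed between two disjoint vehicle sample sets.

    The resulting distribution is the no-treatment null used to judge the
    Z >= 2 gate: most genes exceeding it do so by chance, which is
    acceptable because D_max only chooses a counting boundary.
    """
    return dmax_table(list(vehicle_rep_a), list(vehicle_rep_b),
                      min_reads=min_reads, bin_size=bin_size)


# ---------------------------------------------------------------------------
# Downstream differential expression


def downstream_boundary(
    dmax_z: float,
    dmax_codon: int,
    default_codon: int = DEFAULT_BOUNDARY_CODON,
    z_min: float = DEFAULT_Z_MIN,
) -> int:
    """5' boundary codon for downstream counting.

    Genes passing the Z-gate use their D_max position; all others use
    codon ``default_codon``.  Counting is strictly 3' of the boundary
    (the boundary codon itself is excluded).
    """
    return int(dmax_codon) if dmax_z >= z_min else int(default_codon)


def downstream_counts(codon_counts: np.ndarray, boundary: int) -> int:
    """Sum of counts at codons strictly greater than ``boundary``."""
    if boundary >= len(codon_counts):
        return 0
    return int(codon_counts[max(boundary, 0):].sum())


def differential_downstream(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> pd.DataFrame:
    """Negative-binomial differential expression on a gene x sample matrix.

    ``counts`` has genes as rows and sample ids as columns; ``design``
    has one row per sample with a ``condition`` column containing
    "treatment" / "vehicle" (>= 2 replicates each).  Size factors are
    median-of-ratios over the submitted matrix, gene-wise dispersions are
    shrunk toward a fitted mean-dispersion trend, and a two-sided Wald
    test gives p-values corrected by Benjamini-Hochberg (DESeq2 model,
    via pydeseq2).  Genes with all-zero counts are excluded and reported
    via the ``tested`` flag.

    Returns a frame indexed by gene with columns log2_fold_change
    (treatment vs vehicle), p_value, fdr, significant_decrease.
    """
    missing = set(design.index) - set(counts.columns)
    if missing:
        raise ValueError(f"design rows without count columns: {sorted(missing)}")
    for cond in ("treatment", "vehicle"):
        if (design["condition"] == cond).sum() < 2:
            raise ValueError(f"need >= 2 replicates of {cond}")

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    mat = counts[design.index].T  # samples x genes
    nonzero = mat.sum(axis=0) > 0
    meta = design[["condition"]].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=mat.loc[:, nonzero].astype(int),
            metadata=meta,
            design="~condition",
            refit_cooks=True,
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "treatment", "vehicle"], quiet=True
        )
        stats.summary()
    res = stats.results_df
    out = pd.DataFrame(index=counts.index)
    out["log2_fold_change"] = res["log2FoldChange"].reindex(out.index)
    out["p_value"] = res["pvalue"].reindex(out.index)
    out["fdr"] = res["padj"].reindex(out.index)
    out["tested"] = out.index.isin(res.index)
    out["significant_decrease"] = (
        (out["fdr"] < fdr_max) & (out["log2_fold_change"] < 0)
    ).fillna(False)
    return out


# ---------------------------------------------------------------------------
# Stall peak calling and the full gene call


def call_stall_codons(
    treatment_maps: Sequence[CodonCounts],
    vehicle_maps: Sequence[CodonCounts],
    gene_id: str,
    boundary: int,
    totals_t: Sequence[int],
    totals_v: Sequence[int],
    shoulder: float = 0.5,
) -> List[int]:
    """Automatic stall-peak calls from the RPM difference profile.

    The mean treatment RPM minus mean vehicle RPM is computed per codon
    over codons at or 5' of the boundary; the highest-difference codon is
    the primary stall, and codons reaching at least ``shoulder`` of that
    peak difference are reported with it (stalls can span several
    codons).  Returns 1-based codons, the primary peak first.
    """
    rpm_t = np.mean([cm[gene_id] / tot * 1e6
                     for cm, tot in zip(treatment_maps, totals_t)], axis=0)
    rpm_v = np.mean([cm[gene_id] / tot * 1e6
                     for cm, tot in zip(vehicle_maps, totals_v)], axis=0)
    diff = (rpm_t - rpm_v)[:boundary]
    if diff.size == 0 or diff.max() <= 0:
        return []
    peak = diff.max()
    codons = [int(i) + 1 for i in np.nonzero(diff >= shoulder * peak)[0]]
    primary = int(np.argmax(diff)) + 1
    # primary (highest-difference) codon first, shoulders after, 5' to 3'
    return [primary] + [c for c in codons if c != primary]


@dataclass
class StallCallConfig:
    z_min: float = DEFAULT_Z_MIN
    fdr_max: float = DEFAULT_FDR_MAX
    default_codon: int = DEFAULT_BOUNDARY_CODON
    bin_size: int = DEFAULT_BIN_SIZE
    min_reads: int = DEFAULT_MIN_READS
    peak_shoulder: float = 0.5


def call_sensitive(
    treatment_maps: Sequence[CodonCounts],
    vehicle_maps: Sequence[CodonCounts],
    config: StallCallConfig = StallCallConfig(),
) -> pd.DataFrame:
    """The full per-gene stall call.

    Pipeline: pooled CFR curves -> D_max and local Z -> per-gene
    downstream boundary -> per-replicate downstream counts ->
    negative-binomial test -> sensitive iff Z > z_min, FDR < fdr_max and
    log2 fold change < 0.  Genes whose CDS is shorter than the default
    boundary and that fail the Z-gate have no testable downstream region;
    they are excluded (``tested`` False).

    Returns a frame indexed by gene_id with D_max fields, boundary,
    differential results, the sensitive call and automatic stall-peak
    codons.
    """
    dt = dmax_table(treatment_maps, vehicle_maps,
                    min_reads=config.min_reads, bin_size=config.bin_size)
    n_codons = {}
    all_maps = list(treatment_maps) + list(vehicle_maps)
    for gene in dt.index:
        n_codons[gene] = len(all_maps[0][gene])

    boundaries = {}
    for gene, row in dt.iterrows():
        b = downstream_boundary(row["zscore"], row["dmax_codon"],
                                config.default_codon, config.z_min)
        boundaries[gene] = b
    testable = [g for g, b in boundaries.items() if b < n_codons[g]]

    sample_ids = ([f"treatment_{i+1}" for i in range(len(treatment_maps))]
                  + [f"vehicle_{i+1}" for i in range(len(vehicle_maps))])
    conditions = (["treatment"] * len(treatment_maps)
                  + ["vehicle"] * len(vehicle_maps))
    counts = pd.DataFrame(
        {sid: [downstream_counts(cm[g], boundaries[g]) for g in testable]
         for sid, cm in zip(sample_ids, all_maps)},
        index=pd.Index(testable, name="gene_id"),
    )
    design = pd.DataFrame({"condition": conditions}, index=sample_ids)
    de = differential_downstream(counts, design, fdr_max=config.fdr_max)

    totals_t = [sum(int(v.sum()) for v in cm.values()) for cm in treatment_maps]
    totals_v = [sum(int(v.sum()) for v in cm.values()) for cm in vehicle_maps]

    out = dt.copy()
    out["boundary_codon"] = pd.Series(boundaries)
    out = out.join(de, how="left")
    out["tested"] = out["tested"].fillna(False).astype(bool)
    out["sensitive"] = (
        (out["zscore"] > config.z_min)
        & (out["fdr"] < config.fdr_max)
        & (out["log2_fold_change"] < 0)
    ).fillna(False)
    stall_codons = {}
    for gene in out.index[out["sensitive"]]:
        stall_codons[gene] = call_stall_codons(
            treatment_maps, vehicle_maps, gene, boundaries[gene],
            totals_t, totals_v, shoulder=config.peak_shoulder,
        )
    out["stall_codons"] = [
        ",".join(map(str, stall_codons.get(g, []))) for g in out.index
    ]
    return out


# ---------------------------------------------------------------------------
# Center of density


def center_of_density(codon_counts: np.ndarray, omit_first: int = 0) -> float:
    """Count-weighted mean codon position (1-based).

    ``omit_first`` drops the first N codons before averaging; reads must
    remain in the analyzed span.
    """
    kept = codon_counts[omit_first:]
    total = kept.sum()
    if total <= 0:
        raise ValueError("no reads in the analyzed span")
    positions = np.arange(omit_first + 1, len(codon_counts) + 1)
    return float((positions * kept).sum() / total)


def cod_change_zscores(
    treatment_maps: Sequence[CodonCounts],
    vehicle_maps: Sequence[CodonCounts],
    omit_first: int = 0,
    min_reads: int = DEFAULT_MIN_READS,
    bin_size: int = DEFAULT_BIN_SIZE,
    cod_z_min: float = DEFAULT_COD_Z_MIN,
) -> pd.DataFrame:
    """Treatment-vs-vehicle center-of-density shifts with local Z-scores.

    ``delta`` = mean position (treatment) - mean position (vehicle), in
    codons; a 5' shift under treatment gives delta < 0.  Outliers are
    flagged at |Z| >= ``cod_z_min``.
    """
    pooled_t = pooled_codon_counts(treatment_maps)
    pooled_v = pooled_codon_counts(vehicle_maps)
    rows = []
    for tid in sorted(set(pooled_t) & set(pooled_v)):
        ct, cv = pooled_t[tid], pooled_v[tid]
        if len(ct) <= omit_first:
            continue
        nt_, nv = int(ct[omit_first:].sum()), int(cv[omit_first:].sum())
        if nt_ < min_reads or nv < min_reads:
            continue
        mt = center_of_density(ct, omit_first)
        mv = center_of_density(cv, omit_first)
        rows.append((tid, mt, mv, mt - mv, nt_ + nv))
    df = pd.DataFrame(rows, columns=[
        "gene_id", "mean_position_treatment", "mean_position_vehicle",
        "delta", "expression"]).set_index("gene_id")
    df["omit_first"] = omit_first
    if len(df):
        df["zscore"] = local_zscore(df["delta"], df["expression"], bin_size)
    else:
        df["zscore"] = pd.Series(dtype=float)
    df["outlier"] = df["zscore"].abs() >= cod_z_min
    return df
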