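"""Expression-binned (local) Z-scores.

Sampling noise in per-gene statistics (CFR divergence, center-of-density
shift, TE change) scales with read depth, so a global Z-score would flag
low-coverage genes preferentially.  Instead genes are sorted by
expression, grouped into bins of 300, and each gene's value is
standardized against the mean and sample SD of the *other* genes in its
bin (leave-one-out), so a gene's own extreme value does not mask itself.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 300


def assign_expression_bins(expression: pd.Series, bin_size: int = DEFAULT_BIN_SIZE
                           ) -> pd.Series:
    """Bin labels (0 = highest expression) for each gene.

    Genes are sorted by expression descending (ties broken by index for
    determinism) and cut into consecutive bins of ``bin_size``.  A final
    remainder smaller than ``bin_size / 2`` is absorbed into the previous
    bin; a larger remainder stands as its own bin.
    """
    n = len(expression)
    if n == 0:
        raise ValueError("no genes to bin")
    order = expression.sort_values(ascending=False, kind="mergesort").index
    n_bins = max(1, n // bin_size)
    if n < bin_size:
        warnings.warn(f"only {n} genes: using a single expression bin")
    labels = np.minimum(np.arange(n) // bin_size, n_bins - 1)
    remainder = n - n_bins * bin_size
    if remainder >= bin_size / 2:
        labels[n_bins * bin_size:] = n_bins  # remainder stands alone
    return pd.Series(labels, index=order).reindex(expression.index)


def local_zscore(
    values: pd.Series,
    expression: pd.Series,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.Series:
    """Leave-one-out Z-score of ``values`` within expression bins.

    For gene *i* in a bin of *n* genes, Z_i = (v_i - mean_{-i}) / sd_{-i},
    where mean and sample SD are computed over the other n-1 genes.  Bins
    whose leave-one-out SD is zero yield Z = 0.
    """
    values = values.astype(float)
    expression = expression.reindex(values.index)
    bins = assign_expression_bins(expression, bin_size)
    z = pd.Series(np.nan, index=values.index, dtype=float)
    for _, idx in values.groupby(bins).groups.items():
        v = values.loc[idx].to_numpy()
        n = v.size
        if n < 3:
            z.loc[idx] = 0.0
            continue
        s = v.sum()
        ss = (v * v).sum()
        loo_mean = (s - v) / (n - 1)
        # leave-one-out sample variance over n-1 values (ddof=1 -> n-2)
        loo_var = (ss - v * v - (n - 1) * loo_mean ** 2) / (n - 2)
        loo_sd = np.sqrt(np.maximum(loo_var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            zi = np.where(loo_sd > 0, (v - loo_mean) / loo_sd, 0.0)
        z.loc[idx] = zi
    return z
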