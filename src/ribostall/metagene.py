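"""Metagene profiles: normalized mean reads (NMR) around start/stop codons.

The NMR at an offset is the across-transcript mean of (count at that
position) / (mean CDS read density of the transcript).  A uniformly
covered transcript therefore contributes 1.0 at every CDS offset, and a
library of such transcripts yields a flat profile at 1.0 — deviations
(start/stop peaks, 3-nt periodicity, UTR depletion) are the quality
surfaces of a footprint library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ingest import ReadMap
from .transcriptome import ReferenceSet

DEFAULT_MIN_CDS_LEN = 600  # nt; keeps default windows fully inside the CDS


@dataclass
class MetageneProfile:
    anchor: str                 # "start" | "stop"
    offsets: np.ndarray         # nt offsets relative to the anchor
    nmr: np.ndarray
    n_transcripts: np.ndarray   # transcripts contributing per offset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "anchor": self.anchor,
            "offset": self.offsets,
            "nmr": self.nmr,
            "n_transcripts": self.n_transcripts,
        })


def _anchor_position(t, anchor: str) -> int:
    # start: offset 0 = first nt of the start codon.
    # stop: offset 0 = first nt of the stop codon.
    if anchor == "start":
        return t.cds_start
    if anchor == "stop":
        return t.cds_end - 3
    raise ValueError(f"unknown anchor: {anchor}")


def longest_cds_per_gene(reference: ReferenceSet) -> List[str]:
    """One transcript per gene: the one with the longest CDS.

    Ties break toward the lexicographically smaller transcript id.
    """
    best: Dict[str, Tuple[int, str]] = {}
    for t in reference:
        key = (-t.cds_len, t.transcript_id)
        if t.gene_id not in best or key < best[t.gene_id]:
            best[t.gene_id] = key
    return sorted(tid for _, tid in best.values())


def normalized_mean_profile(
    readmaps: Sequence[ReadMap],
    reference: ReferenceSet,
    anchor: str = "start",
    window: Tuple[int, int] = (-50, 300),
    min_cds_len: int = DEFAULT_MIN_CDS_LEN,
    transcript_ids: Optional[Sequence[str]] = None,
) -> MetageneProfile:
    """Average NMR profile over transcripts, pooling the given readmaps.

    A transcript is included when its CDS is at least ``min_cds_len`` nt,
    the window fits inside the transcript, and it has nonzero CDS reads
    (zero-read transcripts have no defined density and are excluded rather
    than contributing 0/0).  When ``transcript_ids`` is None, the longest
    CDS per gene is used.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window lo > hi")
    if transcript_ids is None:
        transcript_ids = longest_cds_per_gene(reference)
    offsets = np.arange(lo, hi + 1)
    total = np.zeros(offsets.size, dtype=float)
    n_used = np.zeros(offsets.size, dtype=np.int64)
    any_candidate = False
    for tid in transcript_ids:
        t = reference[tid]
        if t.cds_len < min_cds_len:
            continue
        apos = _anchor_position(t, anchor)
        if apos + lo < 0 or apos + hi >= t.length:
            continue
        any_candidate = True
        pooled = None
        for rm in readmaps:
            vec = rm.counts.get(tid)
            if vec is None:
                continue
            pooled = vec if pooled is None else pooled + vec
        if pooled is None:
            continue
        cds_total = pooled[t.cds_start:t.cds_end].sum()
        if cds_total == 0:
            continue
        density = cds_total / t.cds_len
        total += pooled[apos + lo: apos + hi + 1] / density
        n_used += 1
    if not any_candidate:
        raise ValueError(
            "metagene window fits no transcript; shrink the window or "
            "lower min_cds_len"
        )
    nmr = np.divide(total, n_used, out=np.zeros_like(total),
                    where=n_used > 0)
    return MetageneProfile(anchor=anchor, offsets=offsets, nmr=nmr,
                           n_transcripts=n_used)


def smooth_profile(profile: MetageneProfile, k: int = 3) -> MetageneProfile:
    """Centered moving average over k positions (k odd); edges truncate."""
    if k % 2 != 1 or k < 1:
        raise ValueError("k must be odd and >= 1")
    if k == 1:
        return profile
    half = k // 2
    n = profile.nmr.size
    smoothed = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        smoothed[i] = profile.nmr[lo:hi].mean()
    return MetageneProfile(profile.anchor, profile.offsets.copy(), smoothed,
                           profile.n_transcripts.copy())


def periodicity_autocorrelation(nmr: np.ndarray, max_lag: int = 9) -> np.ndarray:
    """Autocorrelation of the mean-subtracted profile at lags 1..max_lag.

    Footprint libraries show a period-3 signature: the lag-3 (and 6, 9)
    coefficients exceed the off-phase lags.
    """
    x = nmr - nmr.mean()
    denom = (x * x).sum()
    if denom == 0:
        return np.zeros(max_lag)
    return np.array([(x[:-lag] * x[lag:]).sum() / denom
                     for lag in range(1, max_lag + 1)])
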