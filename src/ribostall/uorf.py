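"""Upstream ORF enumeration, quantification and replicate-consistency test.

A uORF is an AUG whose A lies in the 5'UTR, paired with the first
in-frame stop codon anywhere downstream in the transcript (the stop may
fall inside the main CDS; such uORFs are flagged as CDS-overlapping).
Compound-induced stalling on a uORF would show as a treatment-consistent
increase in footprints over the uORF span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .transcriptome import STOP_CODONS, TranscriptModel


@dataclass(frozen=True)
class UORF:
    transcript_id: str
    start_nt: int       # 0-based position of the A of the AUG; < utr5_len
    stop_nt: int        # 0-based position of the first nt of the stop codon
    n_codons: int       # codon count including the stop codon
    overlaps_cds: bool

    @property
    def span(self) -> Tuple[int, int]:
        """Half-open nt interval covered by the uORF, stop included."""
        return self.start_nt, self.stop_nt + 3


def enumerate_uorfs(transcript: TranscriptModel) -> List[UORF]:
    """All uORFs of one transcript, 5' to 3' by start position.

    Every ATG starting in the 5'UTR is extended codon by codon until the
    first in-frame stop; ATGs with no in-frame stop before the
    transcript's end are excluded.  Nested and overlapping uORFs are all
    reported.  Requires the transcript sequence.
    """
    seq = transcript.sequence.upper()
    if not seq:
        raise ValueError(f"{transcript.transcript_id} has no sequence")
    out: List[UORF] = []
    for start in range(transcript.utr5_len - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for pos in range(start, len(seq) - 2, 3):
            if seq[pos:pos + 3] in STOP_CODONS:
                out.append(UORF(
                    transcript_id=transcript.transcript_id,
                    start_nt=start,
                    stop_nt=pos,
                    n_codons=(pos - start) // 3 + 1,
                    overlaps_cds=pos + 3 > transcript.utr5_len,
                ))
                break
    return out


def quantify_uorf(counts: np.ndarray, uorf: UORF
                  ) -> Tuple[int, Optional[np.ndarray]]:
    """Footprints on a uORF and their reading-frame distribution.

    ``counts`` is the transcript's nucleotide-resolution P-site vector.
    Returns (read_count, frame_fractions), where frame_fractions[f] is
    the proportion of the uORF's reads at positions congruent to
    start_nt + f modulo 3; None when the span has no reads.
    """
    lo, hi = uorf.span
    span = counts[lo:hi]
    total = int(span.sum())
    if total == 0:
        return 0, None
    frames = np.zeros(3)
    for f in range(3):
        frames[f] = span[f::3].sum()
    return total, frames / total


def uorf_consistency_test(
    uorf_counts: pd.DataFrame,
    design: pd.DataFrame,
    total_cds_reads: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Flag uORFs with a replicate-consistent treatment increase.

    Counts are normalized to reads per million CDS-aligned reads per
    sample.  A uORF is flagged when every treatment replicate's
    normalized count strictly exceeds every vehicle replicate's (complete
    rank separation) — under the null with 3v3 replicates this happens
    for 1 of the C(6,3)=20 orderings.  ``log2_fc`` compares normalized
    condition means with a pseudocount.
    """
    t_cols = design.index[design["condition"] == "treatment"]
    v_cols = design.index[design["condition"] == "vehicle"]
    norm = uorf_counts / total_cds_reads.reindex(uorf_counts.columns) * 1e6
    t_min = norm[t_cols].min(axis=1)
    v_max = norm[v_cols].max(axis=1)
    out = pd.DataFrame(index=uorf_counts.index)
    out["flagged"] = t_min > v_max
    out["log2_fc"] = np.log2(
        (norm[t_cols].mean(axis=1) + pseudocount)
        / (norm[v_cols].mean(axis=1) + pseudocount)
    )
    return out


def uorf_table(
    transcripts: Sequence[TranscriptModel],
    readmaps: Optional[Dict[str, "np.ndarray"]] = None,
) -> pd.DataFrame:
    """Enumerate uORFs across transcripts into one frame."""
    rows = []
    for t in transcripts:
        if not t.sequence:
            continue
        for u in enumerate_uorfs(t):
            rows.append((u.transcript_id, u.start_nt, u.stop_nt,
                         u.n_codons, u.overlaps_cds))
    return pd.DataFrame(rows, columns=[
        "transcript_id", "start_nt", "stop_nt", "n_codons", "overlaps_cds"])
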