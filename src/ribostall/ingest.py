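"""Alignment ingestion: P-site assignment, read maps and codon maps.

Footprint alignments arrive in transcriptome coordinates (SAM/BAM or a
4-column TSV).  This module applies the read-length window (26-34 nt
inclusive by default), the multi-mapping policy (discard reads with more
than five equal-best sites, keep one deterministic site otherwise),
assigns each footprint's P-site by a fixed offset from the 5' end
(+14 nt by default, which places the first major footprint peak at
nucleotide +2 relative to the start codon), and accumulates per-transcript
count vectors at nucleotide and codon resolution.  mRNA-seq fragments are
not footprints and get no offset.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .transcriptome import ReferenceSet

DEFAULT_PSITE_OFFSET = 14
DEFAULT_MIN_LEN = 26
DEFAULT_MAX_LEN = 34
DEFAULT_MAX_SITES = 5

CodonCounts = Dict[str, np.ndarray]


@dataclass(frozen=True)
class AlignmentRecord:
    """One best-stratum alignment of one read."""

    read_id: str
    transcript_id: str
    pos5: int          # 0-based transcript position of the read 5' end
    read_len: int
    n_best_sites: int = 1


@dataclass
class DropTally:
    """Read accounting for one sample; conservation is asserted downstream."""

    n_input_reads: int = 0
    n_placed: int = 0
    n_length_filtered: int = 0
    n_multimap_discarded: int = 0
    n_out_of_bounds: int = 0
    n_off_reference: int = 0
    n_reverse_strand: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)

    def check_conservation(self) -> None:
        dropped = (self.n_length_filtered + self.n_multimap_discarded
                   + self.n_out_of_bounds + self.n_off_reference
                   + self.n_reverse_strand)
        if self.n_input_reads != self.n_placed + dropped:
            raise AssertionError(
                f"read conservation violated: {self.n_input_reads} in, "
                f"{self.n_placed} placed, {dropped} dropped"
            )


@dataclass
class ReadMap:
    """Per-sample, per-transcript counts at nucleotide resolution.

    For ribo-seq samples the index is the inferred P-site position; for
    mRNA-seq it is the fragment 5' end.
    """

    sample_id: str
    assay: str  # "ribo" | "mrna"
    counts: Dict[str, np.ndarray]
    total_cds_reads: int = 0
    tally: DropTally = field(default_factory=DropTally)

    def compute_total_cds_reads(self, reference: ReferenceSet) -> int:
        total = 0
        for tid, vec in self.counts.items():
            t = reference[tid]
            total += int(vec[t.cds_start:t.cds_end].sum())
        self.total_cds_reads = total
        return total


def read_alignments_tsv(path: str | Path) -> List[AlignmentRecord]:
    """Read a 4/5-column alignment TSV.

    Columns: read_id, transcript_id, pos5, read_len[, n_best_sites].
    """
    df = pd.read_csv(path, sep="\t")
    has_sites = "n_best_sites" in df.columns
    return [
        AlignmentRecord(
            read_id=str(r.read_id),
            transcript_id=str(r.transcript_id),
            pos5=int(r.pos5),
            read_len=int(r.read_len),
            n_best_sites=int(r.n_best_sites) if has_sites else 1,
        )
        for r in df.itertuples()
    ]


def read_alignments_sam(path: str | Path, tally: Optional[DropTally] = None
                        ) -> List[AlignmentRecord]:
    """Read best-stratum alignments from SAM/BAM in transcript coordinates.

    The leftmost aligned position is taken as the 5' end (transcriptome
    alignments are forward-strand); reverse-strand records are discarded
    and tallied.  When no site-count tag is present, n_best_sites is the
    number of emitted records per read name.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    by_read: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    n_reverse = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                n_reverse += 1
                continue
            by_read[aln.query_name].append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    transcript_id=aln.reference_name,
                    pos5=aln.reference_start,
                    read_len=aln.query_length or aln.infer_read_length() or 0,
                )
            )
    if tally is not None:
        tally.n_reverse_strand += n_reverse
    out: List[AlignmentRecord] = []
    for read_id, recs in by_read.items():
        n = len(recs)
        for r in recs:
            out.append(AlignmentRecord(r.read_id, r.transcript_id, r.pos5,
                                       r.read_len, n_best_sites=n))
    return out


def filter_read_lengths(
    alignments: Iterable[AlignmentRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> List[AlignmentRecord]:
    """Keep alignments with min_len <= read_len <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [a for a in alignments if min_len <= a.read_len <= max_len]


def apply_multimap_policy(
    alignments: Iterable[AlignmentRecord],
    max_sites: int = DEFAULT_MAX_SITES,
) -> Tuple[List[AlignmentRecord], int]:
    """Resolve equal-best multi-mapping reads.

    Reads whose best stratum spans more than ``max_sites`` sites are
    discarded entirely (they map to repetitive, low-complexity sequence).
    Surviving reads keep exactly one site, chosen deterministically as the
    first by (transcript_id, pos5).

    Returns ``(records, n_reads_discarded)``.
    """
    groups: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        groups[a.read_id].append(a)
    kept: List[AlignmentRecord] = []
    n_discarded = 0
    for read_id, group in groups.items():
        n_sites = max(max(a.n_best_sites for a in group), len(group))
        if n_sites > max_sites:
            n_discarded += 1
            continue
        best = min(group, key=lambda a: (a.transcript_id, a.pos5))
        kept.append(AlignmentRecord(best.read_id, best.transcript_id,
                                    best.pos5, best.read_len, n_sites))
    return kept, n_discarded


def assign_psite(pos5: int, offset: int = DEFAULT_PSITE_OFFSET) -> int:
    """P-site position = 5'-end position + offset."""
    return pos5 + offset


def build_readmap(
    alignments: Iterable[AlignmentRecord],
    reference: ReferenceSet,
    sample_id: str,
    assay: str = "ribo",
    offset: int = DEFAULT_PSITE_OFFSET,
    tally: Optional[DropTally] = None,
) -> ReadMap:
    """Accumulate P-site-assigned counts into per-transcript vectors.

    ``alignments`` must already be length-filtered and multimap-resolved.
    Alignments whose P-site falls outside the transcript, or that point at
    an unknown transcript, are dropped and tallied.  mRNA-seq maps should
    be built with ``offset=0`` (fragment 5' ends, no P-site inference).
    """
    if tally is None:
        tally = DropTally()
    counts: Dict[str, np.ndarray] = {}
    for a in alignments:
        if a.transcript_id not in reference:
            tally.n_off_reference += 1
            continue
        t = reference[a.transcript_id]
        p = assign_psite(a.pos5, offset)
        if p < 0 or p >= t.length:
            tally.n_out_of_bounds += 1
            continue
        vec = counts.get(a.transcript_id)
        if vec is None:
            vec = np.zeros(t.length, dtype=np.int64)
            counts[a.transcript_id] = vec
        vec[p] += 1
        tally.n_placed += 1
    rm = ReadMap(sample_id=sample_id, assay=assay, counts=counts, tally=tally)
    rm.compute_total_cds_reads(reference)
    return rm


def ingest_sample(
    alignments: Iterable[AlignmentRecord],
    reference: ReferenceSet,
    sample_id: str,
    assay: str = "ribo",
    offset: int = DEFAULT_PSITE_OFFSET,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_sites: int = DEFAULT_MAX_SITES,
) -> ReadMap:
    """Full per-sample pipeline: length filter, multimap policy, readmap.

    mRNA-seq samples skip the length filter and the P-site offset.
    """
    alignments = list(alignments)
    tally = DropTally(n_input_reads=len(alignments))
    # recount in read units, not alignment units
    tally.n_input_reads = len({a.read_id for a in alignments})
    if assay == "ribo":
        kept = filter_read_lengths(alignments, min_len, max_len)
        tally.n_length_filtered = (len({a.read_id for a in alignments})
                                   - len({a.read_id for a in kept}))
    else:
        kept = alignments
        offset = 0
    resolved, n_mm = apply_multimap_policy(kept, max_sites)
    tally.n_multimap_discarded = n_mm
    rm = build_readmap(resolved, reference, sample_id, assay, offset, tally)
    rm.tally.check_conservation()
    return rm


def collapse_to_codons(readmap: ReadMap, reference: ReferenceSet) -> CodonCounts:
    """Sum nucleotide counts into 1-based CDS codon bins.

    Codon *k* collects counts on ``[utr5_len + 3(k-1), utr5_len + 3k)``;
    counts outside the CDS are excluded.
    """
    out: CodonCounts = {}
    for tid, vec in readmap.counts.items():
        t = reference[tid]
        cds = vec[t.cds_start:t.cds_end]
        out[tid] = cds.reshape(t.n_codons, 3).sum(axis=1)
    return out


def normalize_rpm(counts: np.ndarray, total_cds_reads: int) -> np.ndarray:
    """Reads per million CDS-aligned reads: count / total * 1e6."""
    if total_cds_reads <= 0:
        raise ValueError("total_cds_reads must be positive for RPM")
    return counts.astype(float) / total_cds_reads * 1e6


def write_readmap_tsv(readmap: ReadMap, path: str | Path) -> None:
    """Write a sparse TSV (sample_id, transcript_id, position, count)."""
    rows = []
    for tid in sorted(readmap.counts):
        vec = readmap.counts[tid]
        nz = np.nonzero(vec)[0]
        for pos in nz:
            rows.append((readmap.sample_id, tid, int(pos), int(vec[pos])))
    pd.DataFrame(rows, columns=["sample_id", "transcript_id", "position", "count"]
                 ).to_csv(path, sep="\t", index=False)


def read_readmap_tsv(path: str | Path, reference: ReferenceSet,
                     assay: str = "ribo") -> ReadMap:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return ReadMap(sample_id=Path(path).stem, assay=assay, counts={})
    sample_id = str(df["sample_id"].iloc[0])
    counts: Dict[str, np.ndarray] = {}
    for tid, grp in df.groupby("transcript_id"):
        t = reference[str(tid)]
        vec = np.zeros(t.length, dtype=np.int64)
        vec[grp["position"].to_numpy()] = grp["count"].to_numpy()
        counts[str(tid)] = vec
    rm = ReadMap(sample_id=sample_id, assay=assay, counts=counts)
    rm.compute_total_cds_reads(reference)
    return rm
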