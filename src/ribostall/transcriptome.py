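"""Reference transcriptome assembly and representative-isoform selection.

Transcript records are assembled from per-region sequences (5'UTR, CDS,
3'UTR) into a single transcript-local coordinate frame that every other
stage of the pipeline shares.  Coordinates are 0-based, half-open and
transcript-local: the CDS occupies ``[utr5_len, utr5_len + cds_len)`` and
codon *k* (1-based, codon 1 = start codon) occupies nucleotides
``[utr5_len + 3*(k-1), utr5_len + 3*k)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus region lengths.

    ``sequence`` may be empty when only region lengths are known (length
    tables are sufficient for all counting operations; the sequence is
    required only for uORF scanning).
    """

    transcript_id: str
    gene_id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3

    def codon_span(self, k: int) -> Tuple[int, int]:
        """Nucleotide half-open interval of 1-based codon ``k``."""
        start = self.utr5_len + 3 * (k - 1)
        return start, start + 3

    def validation_errors(self) -> List[str]:
        errs = []
        if self.sequence and len(self.sequence) != self.length:
            errs.append("sequence length != sum of region lengths")
        if self.cds_len % 3 != 0:
            errs.append("CDS not multiple of 3")
        if self.cds_len < 6:
            errs.append("CDS shorter than start + one codon")
        if self.utr5_len < 0 or self.utr3_len < 0:
            errs.append("negative UTR length")
        return errs


class ReferenceSet:
    """An id-keyed collection of :class:`TranscriptModel` records."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._transcripts: Dict[str, TranscriptModel] = {}
        for tm in transcripts:
            if tm.transcript_id in self._transcripts:
                raise ValueError(f"duplicate transcript id: {tm.transcript_id}")
            self._transcripts[tm.transcript_id] = tm

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    @property
    def ids(self) -> List[str]:
        return list(self._transcripts)

    def subset(self, ids: Sequence[str]) -> "ReferenceSet":
        return ReferenceSet(self._transcripts[i] for i in ids)

    def length_table(self) -> pd.DataFrame:
        rows = [
            (t.transcript_id, t.gene_id, t.utr5_len, t.cds_len, t.utr3_len)
            for t in self
        ]
        return pd.DataFrame(
            rows, columns=["transcript_id", "gene_id", "utr5_len", "cds_len", "utr3_len"]
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(t.sequence), id=t.transcript_id,
                      description=t.gene_id)
            for t in self
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_length_table(self, path: str | Path) -> None:
        self.length_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fasta(cls, fasta_path: str | Path, table_path: str | Path) -> "ReferenceSet":
        table = pd.read_csv(table_path, sep="\t")
        seqs = {}
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate transcript id in FASTA: {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()
        transcripts = [
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                sequence=seqs.get(row.transcript_id, ""),
                utr5_len=int(row.utr5_len),
                cds_len=int(row.cds_len),
                utr3_len=int(row.utr3_len),
            )
            for row in table.itertuples()
        ]
        return cls(transcripts)

    @classmethod
    def from_length_table(cls, table: pd.DataFrame) -> "ReferenceSet":
        return cls(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                sequence="",
                utr5_len=int(row.utr5_len),
                cds_len=int(row.cds_len),
                utr3_len=int(row.utr3_len),
            )
            for row in table.itertuples()
        )


_BIOMART_HEADER = re.compile(r"^([^|\s]+)\|([^|\s]+)")


def read_region_fasta(path: str | Path) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Read one per-region multi-FASTA.

    Returns ``(id -> sequence, id -> gene)``.  Headers in the BioMart
    dialect ``transcript_id|gene_id`` populate the gene map; plain headers
    leave it empty for that record (supply a separate id→gene table).
    Records whose sequence is literally ``Sequence unavailable`` (BioMart's
    placeholder for transcripts lacking the region) are treated as absent.
    """
    seqs: Dict[str, str] = {}
    genes: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _BIOMART_HEADER.match(rec.id)
        if m:
            tid, gid = m.group(1), m.group(2)
            genes[tid] = gid
        else:
            tid = rec.id
        if tid in seqs:
            raise ValueError(f"duplicate transcript id in {path}: {tid}")
        seq = str(rec.seq).upper().replace("U", "T")
        if seq and "SEQUENCEUNAVAILABLE" not in seq.replace(" ", ""):
            seqs[tid] = seq
        else:
            seqs[tid] = ""
    return seqs, genes


def assemble_transcripts(
    utr5_records: Mapping[str, str],
    cds_records: Mapping[str, str],
    utr3_records: Mapping[str, str],
    id_to_gene: Mapping[str, str],
) -> Tuple[ReferenceSet, pd.DataFrame]:
    """Concatenate per-region sequences into single transcript records.

    Every transcript id must appear in ``cds_records``; UTR records are
    optional (an absent region has length 0).  Transcripts with annotation
    inconsistencies (CDS not a multiple of 3, CDS < 6 nt) are quarantined
    into the returned rejects table rather than repaired or dropped
    silently.

    Returns ``(reference, rejects)`` where ``rejects`` has columns
    ``transcript_id, reason``.
    """
    accepted: List[TranscriptModel] = []
    rejects: List[Tuple[str, str]] = []
    for tid in cds_records:
        gene = id_to_gene.get(tid, tid)
        utr5 = utr5_records.get(tid, "")
        cds = cds_records[tid]
        utr3 = utr3_records.get(tid, "")
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=gene,
            sequence=utr5 + cds + utr3,
            utr5_len=len(utr5),
            cds_len=len(cds),
            utr3_len=len(utr3),
        )
        errs = tm.validation_errors()
        if errs:
            for e in errs:
                rejects.append((tid, e))
        else:
            accepted.append(tm)
    rejects_df = pd.DataFrame(rejects, columns=["transcript_id", "reason"])
    return ReferenceSet(accepted), rejects_df


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with at least (transcript_id, gene_id, tpm) columns."""
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "gene_id", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    if (df["tpm"] < 0).any():
        raise ValueError("negative TPM in abundance table")
    return df


def select_representative_isoforms(
    abundance: pd.DataFrame,
    min_tpm: float = 1.0,
    mode: str = "best",
    min_fraction: float = 0.1,
) -> List[str]:
    """Select isoforms to carry through the analysis, one mode of two.

    ``mode="best"`` keeps, per gene, the single isoform with maximal TPM,
    included only if that TPM >= ``min_tpm`` (the threshold is inclusive).
    Ties on TPM are broken toward the lexicographically smaller
    transcript_id for determinism.

    ``mode="fraction"`` keeps every isoform contributing at least
    ``min_fraction`` of its gene's summed TPM (an alternative, more
    permissive reference used as a robustness check).

    Output is sorted by gene_id (then transcript_id).
    """
    if abundance.empty:
        raise ValueError("abundance table is empty")
    df = abundance.copy()
    if mode == "best":
        df = df.sort_values(["gene_id", "tpm", "transcript_id"],
                            ascending=[True, False, True], kind="mergesort")
        best = df.groupby("gene_id", sort=True).head(1)
        best = best[best["tpm"] >= min_tpm]
        return best.sort_values(["gene_id", "transcript_id"])["transcript_id"].tolist()
    elif mode == "fraction":
        totals = df.groupby("gene_id")["tpm"].transform("sum")
        keep = df[(totals > 0) & (df["tpm"] >= min_fraction * totals)]
        return keep.sort_values(["gene_id", "transcript_id"])["transcript_id"].tolist()
    raise ValueError(f"unknown isoform selection mode: {mode}")


def filter_fasta_by_ids(
    records: Mapping[str, str], ids: Sequence[str]
) -> Tuple[Dict[str, str], List[str]]:
    """Subset a FASTA mapping to ``ids``, preserving the id-list order.

    Ids absent from the input are not an error: they are omitted from the
    output and returned in the ``missing`` report list.
    """
    out: Dict[str, str] = {}
    missing: List[str] = []
    for tid in ids:
        if tid in records:
            out[tid] = records[tid]
        else:
            missing.append(tid)
    return out, missing
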