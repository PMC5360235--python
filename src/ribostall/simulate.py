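"""Synthetic ribosome-profiling experiments with known stall ground truth.

The generator emulates the signature of a compound-induced elongation
stall: a multiplicative footprint peak at the stall codon, attenuated
density 3' of it (the ``readthrough`` fraction of flux continues past
the stall), 3-nt periodicity within codons, negative-binomial count
noise between replicates, and an mRNA-seq assay that ignores stall
parameters entirely (transcript levels are unchanged by a translation-
step effect).  Every simulated quantity has a closed-form expectation
exposed for oracle tests, and the emitted truth table records exact
per-gene expected changes: the downstream log2 fold change of a stalled
gene is log2(readthrough) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ingest import AlignmentRecord, ReadMap
from .transcriptome import ReferenceSet, TranscriptModel

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOPS = ("TAA", "TAG", "TGA")

DEFAULT_PERIODICITY = (0.70, 0.20, 0.10)


@dataclass
class GeneSpec:
    """Ground-truth generative parameters for one gene."""

    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    base_expression: float         # expected share of CDS footprints (vehicle)
    dispersion: float = 0.05       # NB dispersion of per-gene totals
    stall_codon: Optional[int] = None   # 1-based; None = no stall
    stall_amplitude: float = 0.0   # peak height above baseline (x baseline)
    readthrough: float = 1.0       # fraction of flux continuing 3' of stall
    stall_width: int = 1           # codons covered by the peak
    periodicity_weights: Tuple[float, float, float] = DEFAULT_PERIODICITY
    has_polyA: bool = True
    transcription_fold: float = 1.0  # treatment/vehicle mRNA-level change
    n_paralog_copies: int = 1
    uorf_read_fraction: float = 0.0  # share of footprints on the 5'UTR uORF
    uorf_span: Optional[Tuple[int, int]] = None  # nt half-open, set by generator

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3

    @property
    def stalled(self) -> bool:
        return (self.stall_codon is not None
                and (self.stall_amplitude > 0 or self.readthrough < 1))


def _random_utr(rng: np.random.Generator, length: int, allow_atg: bool) -> str:
    seq = rng.choice(list("ACGT"), size=length)
    s = "".join(seq)
    if not allow_atg:
        # scrub any ATG (and avoid creating new ones) so uorf_rate=0 holds
        while "ATG" in s:
            s = s.replace("ATG", "ACG")
    return s


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    # start + sense codons + stop; no internal in-frame stop
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + str(rng.choice(STOPS))


def simulate_transcriptome(
    n_genes: int,
    seed: int,
    utr5_range: Tuple[int, int] = (30, 120),
    cds_codon_range: Tuple[int, int] = (120, 700),
    utr3_range: Tuple[int, int] = (30, 300),
    uorf_rate: float = 0.0,
    paralog_rate: float = 0.0,
    polyA_neg_rate: float = 0.0,
    expression_sigma: float = 1.2,
    dispersion: float = 0.05,
) -> Tuple[ReferenceSet, List[GeneSpec]]:
    """Random transcript models plus their generative specs.

    Each gene gets one transcript with a valid start/stop CDS, log-normal
    base expression and the given NB dispersion.  A ``uorf_rate``
    fraction carry a translatable AUG + in-frame stop in the 5'UTR (all
    other 5'UTRs contain no ATG); a ``paralog_rate`` fraction get a
    near-identical paralog transcript appended to the reference (the
    source of multi-mapping reads); a ``polyA_neg_rate`` fraction are
    flagged non-poly-adenylated.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    transcripts: List[TranscriptModel] = []
    specs: List[GeneSpec] = []
    for i in range(n_genes):
        gid = f"g{i:05d}"
        tid = f"t{i:05d}"
        utr5_len = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
        n_codons = int(rng.integers(cds_codon_range[0], cds_codon_range[1] + 1))
        utr3_len = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
        has_uorf = bool(rng.random() < uorf_rate) and utr5_len >= 30
        utr5 = _random_utr(rng, utr5_len, allow_atg=False)
        uorf_span = None
        if has_uorf:
            # plant AUG + two sense codons + stop, fully inside the 5'UTR
            start = int(rng.integers(14, utr5_len - 12 + 1))
            insert = "ATG" + "".join(rng.choice(SENSE_CODONS, size=2)) \
                + str(rng.choice(STOPS))
            utr5 = utr5[:start] + insert + utr5[start + 12:]
            uorf_span = (start, start + 12)
        cds = _random_cds(rng, n_codons)
        utr3 = _random_utr(rng, utr3_len, allow_atg=True)
        seq = utr5 + cds + utr3
        base = float(rng.lognormal(mean=0.0, sigma=expression_sigma))
        n_copies = 1
        if rng.random() < paralog_rate:
            n_copies = 2
            # near-identical paralog: ~1% point mutations, same structure
            arr = np.array(list(seq))
            n_mut = max(1, len(seq) // 100)
            pos = rng.choice(len(seq), size=n_mut, replace=False)
            for p in pos:
                arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
            transcripts.append(TranscriptModel(
                transcript_id=f"{tid}p2", gene_id=f"{gid}p2",
                sequence="".join(arr), utr5_len=utr5_len,
                cds_len=3 * n_codons, utr3_len=utr3_len))
        transcripts.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, sequence=seq,
            utr5_len=utr5_len, cds_len=3 * n_codons, utr3_len=utr3_len))
        specs.append(GeneSpec(
            gene_id=gid,
            utr5_len=utr5_len,
            cds_len=3 * n_codons,
            utr3_len=utr3_len,
            base_expression=base,
            dispersion=dispersion,
            has_polyA=not (rng.random() < polyA_neg_rate),
            n_paralog_copies=n_copies,
            uorf_read_fraction=0.05 if has_uorf else 0.0,
            uorf_span=uorf_span,
        ))
    return ReferenceSet(transcripts), specs


def implant_stalls(
    specs: Sequence[GeneSpec],
    n_stalls: int,
    seed: int,
    stall_codon_range: Tuple[int, int] = (16, 60),
    readthrough_range: Tuple[float, float] = (0.1, 0.5),
    stall_amplitude: float = 20.0,
    top_half_expression: bool = True,
) -> List[GeneSpec]:
    """Return a copy of ``specs`` with stalls implanted into n_stalls genes.

    Stall codons are drawn uniformly from ``stall_codon_range`` (most
    observed stalls sit before codon 50, the earliest near codon 16) and
    readthrough uniformly from ``readthrough_range``.  By default stalls
    go into genes of top-half expression, where the detection statistics
    are well powered.
    """
    rng = np.random.default_rng(seed)
    specs = list(specs)
    expr = np.array([s.base_expression for s in specs])
    if top_half_expression:
        eligible = np.nonzero(expr >= np.median(expr))[0]
    else:
        eligible = np.arange(len(specs))
    eligible = [i for i in eligible
                if specs[i].n_codons > stall_codon_range[1] + 10]
    chosen = rng.choice(eligible, size=n_stalls, replace=False)
    out = list(specs)
    for i in chosen:
        out[i] = replace(
            specs[i],
            stall_codon=int(rng.integers(stall_codon_range[0],
                                         stall_codon_range[1] + 1)),
            stall_amplitude=stall_amplitude,
            readthrough=float(rng.uniform(*readthrough_range)),
        )
    return out


def expected_density(spec: GeneSpec, condition: str) -> np.ndarray:
    """Closed-form per-codon expected relative density.

    Vehicle: flat 1 per codon.  Treatment, stalled genes: codons 5' of
    the stall keep density 1; the stall peak (``stall_width`` codons from
    ``stall_codon``) has 1 + stall_amplitude; codons 3' of the peak have
    ``readthrough``.  The vector is a relative shape (not normalized);
    its sum relative to the vehicle sum is the expected whole-CDS count
    change.
    """
    n = spec.n_codons
    dens = np.ones(n)
    if condition == "treatment" and spec.stalled:
        s = spec.stall_codon - 1
        e = min(s + spec.stall_width, n)
        dens[s:e] = 1.0 + spec.stall_amplitude
        dens[e:] = spec.readthrough
    elif condition not in ("treatment", "vehicle"):
        raise ValueError(f"unknown condition: {condition}")
    return dens


def expected_dmax(spec: GeneSpec) -> float:
    """Analytic D_max between the expected treatment and vehicle CFRs."""
    ct = np.cumsum(expected_density(spec, "treatment"))
    cv = np.cumsum(expected_density(spec, "vehicle"))
    diff = ct / ct[-1] - cv / cv[-1]
    return float(diff[np.argmax(np.abs(diff))])


def _nt_probabilities(spec: GeneSpec, transcript_len: int,
                      condition: str, assay: str) -> np.ndarray:
    """Expected P-site probability over transcript nucleotides."""
    p = np.zeros(transcript_len)
    if assay == "mrna":
        # fragments sample the whole transcript uniformly; no stall, no frame
        p[:] = 1.0
        return p / p.sum()
    codon_dens = expected_density(spec, condition)
    w = np.asarray(spec.periodicity_weights, dtype=float)
    w = w / w.sum()
    nt_cds = np.repeat(codon_dens, 3) * np.tile(w, spec.n_codons)
    cds_start = spec.utr5_len
    p[cds_start:cds_start + spec.cds_len] = nt_cds / nt_cds.sum()
    if spec.uorf_read_fraction > 0 and spec.uorf_span is not None:
        lo, hi = spec.uorf_span
        u = np.zeros(hi - lo)
        u[:] = np.tile(w, (hi - lo + 2) // 3)[:hi - lo]
        p[:] *= 1.0 - spec.uorf_read_fraction
        p[lo:hi] = spec.uorf_read_fraction * u / u.sum()
    return p / p.sum()


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def make_design(n_replicates: int = 3, assays: Sequence[str] = ("ribo",),
                timepoint: str = "60min") -> pd.DataFrame:
    """Sample design table: condition x replicate x assay."""
    rows = []
    for assay in assays:
        for cond in ("treatment", "vehicle"):
            for rep in range(1, n_replicates + 1):
                rows.append((f"{assay}_{cond}_{rep}", cond, rep, assay,
                             timepoint))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate",
                                       "assay", "timepoint"]
                        ).set_index("sample_id")


def sim_truth(specs: Sequence[GeneSpec]) -> pd.DataFrame:
    """Ground-truth table: stall flag, codon, exact expected changes."""
    rows = []
    for s in specs:
        whole = np.log2(expected_density(s, "treatment").sum()
                        / expected_density(s, "vehicle").sum()
                        * s.transcription_fold)
        down = np.log2(s.readthrough) if s.stalled else 0.0
        rows.append((s.gene_id, s.stalled, s.stall_codon, s.readthrough,
                     whole, down, s.base_expression, s.has_polyA))
    return pd.DataFrame(rows, columns=[
        "gene_id", "stalled", "stall_codon", "readthrough",
        "expected_log2_ribo_change", "expected_downstream_log2_change",
        "base_expression", "has_polyA"]).set_index("gene_id")


def simulate_experiment(
    reference: ReferenceSet,
    specs: Sequence[GeneSpec],
    design: pd.DataFrame,
    depth: int = 2_000_000,
    seed: int = 0,
    polyA_factor: float = 0.1,
    gene_to_transcript: Optional[Dict[str, str]] = None,
) -> Tuple[Dict[str, ReadMap], pd.DataFrame]:
    """Draw per-sample read maps under the generative model.

    Per gene and sample the total count is NB(depth x allocation x
    condition flux change, dispersion); positions are multinomial under
    the expected nucleotide density.  mRNA-seq samples ignore stall
    parameters and uniformly cover the whole transcript, with
    non-poly-adenylated genes downweighted by ``polyA_factor`` (poly-A
    selection).  Returns (sample_id -> ReadMap, truth table).
    """
    rng = np.random.default_rng(seed)
    if gene_to_transcript is None:
        gene_to_transcript = {s.gene_id: f"t{int(s.gene_id[1:]):05d}"
                              for s in specs}
    base = np.array([s.base_expression for s in specs])
    ribo_alloc = base / base.sum()
    mrna_w = base * np.array([1.0 if s.has_polyA else polyA_factor
                              for s in specs])
    mrna_alloc = mrna_w / mrna_w.sum()

    flux = {}
    for cond in ("treatment", "vehicle"):
        flux[cond] = np.array([
            expected_density(s, cond).sum() / s.n_codons for s in specs
        ])

    readmaps: Dict[str, ReadMap] = {}
    for sample_id, row in design.iterrows():
        assay, cond = row["assay"], row["condition"]
        counts: Dict[str, np.ndarray] = {}
        for i, spec in enumerate(specs):
            if assay == "ribo":
                mean = depth * ribo_alloc[i] * flux[cond][i]
            else:
                mean = depth * mrna_alloc[i]
            if cond == "treatment":
                # a transcript-level change moves both assays together
                mean *= spec.transcription_fold
            total = _nb_draw(rng, mean, spec.dispersion)
            tid = gene_to_transcript[spec.gene_id]
            tlen = reference[tid].length
            vec = np.zeros(tlen, dtype=np.int64)
            if total > 0:
                p = _nt_probabilities(spec, tlen, cond, assay)
                vec = rng.multinomial(total, p).astype(np.int64)
            counts[tid] = vec
        rm = ReadMap(sample_id=str(sample_id), assay=assay, counts=counts)
        rm.compute_total_cds_reads(reference)
        readmaps[str(sample_id)] = rm
    return readmaps, sim_truth(specs)


def emit_alignments(
    readmap: ReadMap,
    reference: ReferenceSet,
    specs: Sequence[GeneSpec],
    seed: int = 0,
    offset: int = 14,
    len_range: Tuple[int, int] = (26, 34),
) -> List[AlignmentRecord]:
    """Expand a ribo read map into 5'-end alignment records.

    Each placed footprint becomes one alignment with pos5 = P-site -
    offset and a read length uniform on ``len_range``; reads from genes
    with paralog copies carry n_best_sites equal to the copy number.
    P-sites closer than ``offset`` to the 5' end cannot be represented as
    a full-length footprint and are skipped.
    """
    rng = np.random.default_rng(seed)
    by_gene = {f"t{int(s.gene_id[1:]):05d}": s for s in specs}
    out: List[AlignmentRecord] = []
    k = 0
    for tid in sorted(readmap.counts):
        vec = readmap.counts[tid]
        spec = by_gene.get(tid)
        n_sites = spec.n_paralog_copies if spec else 1
        for pos in np.nonzero(vec)[0]:
            for _ in range(int(vec[pos])):
                if pos - offset < 0:
                    continue
                out.append(AlignmentRecord(
                    read_id=f"{readmap.sample_id}:r{k}",
                    transcript_id=tid,
                    pos5=int(pos - offset),
                    read_len=int(rng.integers(len_range[0], len_range[1] + 1)),
                    n_best_sites=n_sites,
                ))
                k += 1
    return out


def simulated_abundance(specs: Sequence[GeneSpec],
                        gene_to_transcript: Optional[Dict[str, str]] = None
                        ) -> pd.DataFrame:
    """TPM-style abundance table proportional to base expression."""
    if gene_to_transcript is None:
        gene_to_transcript = {s.gene_id: f"t{int(s.gene_id[1:]):05d}"
                              for s in specs}
    base = np.array([s.base_expression for s in specs])
    tpm = base / base.sum() * 1e6
    return pd.DataFrame({
        "transcript_id": [gene_to_transcript[s.gene_id] for s in specs],
        "gene_id": [s.gene_id for s in specs],
        "tpm": tpm,
    })
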