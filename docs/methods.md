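# Methods

This note documents the models and procedures implemented in
`ribostall`, the parameter defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
conventions that make results reproducible.

## Coordinate conventions

All coordinates are 0-based, half-open and transcript-local. A
transcript is the concatenation 5′UTR + CDS + 3′UTR; the CDS occupies
`[utr5_len, utr5_len + cds_len)` and codon *k* (1-based, codon 1 = the
start codon) occupies nucleotides `[utr5_len + 3(k−1), utr5_len + 3k)`.
These conventions make the P-site offset and the nucleotide-to-codon
collapse pure integer arithmetic with no off-by-one ambiguity.

## Reference assembly and isoform selection

Transcripts are assembled from per-region FASTA inputs (Ensembl BioMart
`transcript_id|gene_id` headers supported). Transcripts with a CDS that
is not a multiple of 3, or shorter than start + one codon, are
quarantined into a rejects table with the reason rather than repaired:
silent repair hides upstream annotation drift. Duplicate transcript ids
are a hard error.

One representative isoform per gene is carried through the analysis:
the isoform with maximal TPM, kept only if TPM ≥ 1 (inclusive). TPM
ties break toward the lexicographically smaller transcript id — the
choice is arbitrary but must be deterministic for reproducible runs. An
alternative `fraction` mode keeps every isoform contributing ≥ 10% of
its gene's summed TPM, as a robustness check that a stricter reference
did not hide targets. Genes whose best isoform has TPM 0 fail the TPM
gate and are excluded even if they have footprints; footprints without
measurable mRNA cannot support the downstream per-gene statistics.

## Read processing

- **Read lengths**: ribo-seq alignments outside 26–34 nt (inclusive)
  are discarded; these bounds are configurable and the filter does not
  apply to mRNA-seq fragments.
- **Multi-mapping**: the aligner is expected to emit all equal-best
  alignments per read. Reads with more than 5 equal-best sites are
  discarded entirely (repetitive/low-complexity sequence); surviving
  reads keep exactly one site, the first by (transcript_id, pos5).
  A deterministic tie-break was preferred over random assignment
  (untestable) and fractional weighting (inconsistent with keeping a
  single best alignment).
- **P-site assignment**: P-site = 5′ end + 14 nt, a single constant
  offset for all read lengths; this places the first major footprint
  peak at nucleotide +2 relative to the start codon. A per-read-length
  offset table would be a compatible extension; the scalar is exposed in
  the config. mRNA-seq fragments are not footprints and get offset 0.
- **Accounting**: every sample's reads satisfy
  `input = placed + length-filtered + multimap-discarded +
  out-of-bounds + off-reference (+ reverse-strand)`, asserted at ingest.
- **RPM**: densities are reads per million CDS-aligned reads
  (count / total CDS reads × 10⁶).

## Metagene profiles

The normalized mean reads (NMR) at an offset is the mean over included
transcripts of (count at offset) / (CDS total / CDS length). One
transcript per gene (longest CDS) is used; transcripts with zero CDS
reads are excluded rather than contributing 0/0. "Sufficient length" is
operationalized as: CDS ≥ `min_cds_len` (default 600 nt) and the window
fully inside the transcript — window containment is the operative
requirement. Default windows are −50..+300 nt around the start and
−300..+50 nt around the stop, covering early-CDS depletion, the
stop-codon peak and the queued-ribosome shoulder. Profiles are computed
per sample and can be pooled; an optional 3-nt moving average is for
display only.

## Local (expression-binned) Z-scores

Per-gene statistics whose sampling noise scales with read depth (D_max,
center-of-density change, TE change, count changes) are standardized
within expression bins: genes sorted by pooled read count descending,
consecutive bins of 300, final remainder absorbed into the previous bin
when smaller than 150 (else standing alone). Each gene is scored
against the mean and sample SD of the *other* genes in its bin
(leave-one-out), so an extreme gene does not mask itself. A bin with
zero leave-one-out SD yields Z = 0.

## CFR, D_max and the sensitive-gene call

CFR curves are built from replicate-pooled codon counts; transcripts
with fewer than `min_reads` (default 64) pooled CDS reads in either
condition are excluded — CFR on sparser transcripts is dominated by
single reads. The default is exposed in the config.

**D_max** is the signed value of (treatment − vehicle) CFR divergence
at the codon of maximal divergence magnitude. This definition is
antisymmetric under swapping the conditions and signs stalls positive;
genes enriched downstream come out negative and cannot pass the
positive Z-gate. On ties the 3′-most codon is reported: the position's
only role is a 5′ boundary for downstream counting, and the most-3′
choice excludes the entire stall region.

The detection gate is deliberately permissive (Z ≥ 2): D_max only
chooses the counting boundary, and genes passing it by chance are
cleaned up by the differential test. Genes with Z ≥ 2 are counted
strictly 3′ of their D_max position; all others strictly 3′ of codon
50. Genes whose CDS is not longer than their boundary have no testable
downstream region and are excluded with a tally.

Downstream counts (per replicate, not pooled) go into a
negative-binomial differential expression test — the DESeq2 model via
`pydeseq2`: median-of-ratios size factors over the submitted matrix,
gene-wise dispersions shrunk toward a fitted mean–dispersion trend,
two-sided Wald test, Benjamini–Hochberg FDR in one family per
timepoint. A gene is **sensitive** iff Z > 2, FDR < 0.1 and log2 fold
change < 0 (decreases only: a stall with unchanged downstream flux does
not reduce protein output). One upstream description of the FDR rule
reads "FDR > 10%"; it is treated as a typo for < 10%, consistent with
the procedural definition used everywhere else.

Stall positions are reported by an automatic peak caller replacing
manual inspection of read plots: on the mean treatment−vehicle RPM
difference over codons 5′ of the boundary, the highest-difference codon
is the primary stall and codons reaching ≥ 50% of that peak are
reported with it (stalls can span several codons). The shoulder
fraction is configurable and reported.

## Center of density

The count-weighted mean codon position per transcript; the
treatment−vehicle difference is Z-scored as above, outliers at |Z| ≥ 3.
Variants omitting the first 50/100/150 codons localize stalls: a stall
inside the omitted span no longer shifts the mean (CFR-free check that
stalling concentrates near the 5′ end). The mean is used rather than
the median because a single-codon pile-up barely moves a median.

## Translational efficiency

TE = normalized footprint count / normalized mRNA count per gene and
condition, whole-CDS (transcript-level claim, not positional).
Normalization is median-of-ratios within each assay; the upstream
procedure did not print its normalization, so this choice is recorded
as an assumption. Genes with zero mRNA counts in a condition are
excluded, not imputed; genes known to be underrepresented by poly-A
selection (e.g. non-poly-adenylated histone transcripts) can be
excluded by flag. The ribo-vs-mRNA decomposition Z-scores each assay's
log2 count change separately; translation-only outliers are
|z_ribo| ≥ 3 with |z_mrna| < 3.

## uORF scan

Every AUG starting in the 5′UTR is paired with the first in-frame stop
codon anywhere downstream; the stop may fall inside the CDS (flagged
`overlaps_cds`) since nothing restricts a uORF's stop to the UTR. No
read-through variants, no non-AUG starts. Counts are P-sites in
`[start, stop+3)`, normalized to RPM by CDS-aligned totals.
"Consistent across replicates" is formalized as strict rank separation:
every treatment replicate above every vehicle replicate. Under the null
with 3v3 replicates this fires for 1 in C(6,3) = 20 orderings, which is
the calibration the tests check.

## The synthetic generator

The generator emulates the stall signature at the level the detection
statistics see: per-gene footprint totals are negative-binomial
(default dispersion 0.05, typical of well-behaved biological
replicates), positions multinomial under a per-codon expected density —
flat for vehicle; for treatment on a stalled gene, baseline 1 up to the
stall, a peak of 1 + amplitude at the stall codon (width 1 by default,
up to 5 to mimic multi-codon stalls), and `readthrough` (the fraction
of translational flux continuing past the stall) beyond it. Within
codons, reads split 70/20/10 across the three frame positions, giving
the 3-nt periodicity of real footprint libraries. mRNA-seq samples
ignore stall parameters entirely and cover the whole transcript
uniformly, with non-poly-adenylated genes downweighted 10× (poly-A
selection). Optional extras: 5′UTR uORFs that attract 5% of a gene's
footprints, near-identical paralogs emitting multi-mapped reads, a
transcription-fold parameter that scales both assays together (control
for the TE decomposition).

Defaults for the implanted-stall experiments: stall codons uniform on
16–60 (stalls concentrate before codon 50, earliest near 16),
readthrough uniform on 0.1–0.5, stalls placed in top-half-expression
genes, amplitude 20. The amplitude reflects observed stall profiles,
where the stall-codon density is tens of times the local baseline; it
was fixed from a power analysis at design time, not fitted. By
construction the expected downstream log2 fold change of a stalled gene
is exactly log2(readthrough), and closed forms for the expected density
and expected D_max are exposed for oracle tests.

What the generator does **not** emulate: sequence-dependent stall
propensity, rRNA contamination, ligation/PCR sequence bias, broader
footprint-size distributions around stalled ribosomes, positional
mRNA-seq coverage bias, and queued-ribosome shoulders (available as an
option concept but off by default). Passing recovery tests therefore
demonstrate that the statistics and thresholds behave as designed under
idealized noise, not that real libraries are free of these artifacts.

## Working scale and determinism

The acceptance computations run at 3,000 genes, 2 conditions × 3
replicates × 2 M reads per sample — ample for every per-gene statistic
(median pooled expression ≈ 2,000 reads/condition for tested genes)
while keeping a full run in tens of seconds. All randomness flows from
explicit seeds; reruns with the same config are byte-identical (floats
printed at fixed precision). Known threshold behavior: sensitivity of
the recovery experiment hovers around 0.85–0.95 across seeds because a
minority of implanted stalls (readthrough near 0.5, late stall, long
CDS) produce CFR divergences at the null's noise floor — these are
genuinely information-poor cases, not a pipeline deficiency.

## Known limitations

- A single constant P-site offset; real libraries benefit from
  per-length calibration.
- The isoform gate ties detection to mRNA quantification quality.
- D_max cannot see stalls with no downstream reads to count (e.g.
  stalls at the stop codon); the center-of-density pathway partially
  covers these.
- The uORF consistency test is rank-based and has low power at 3v3
  replicates by design; it is a screen, not a quantitative test.
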