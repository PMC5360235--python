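import numpy as np
import pytest

from ribostall.transcriptome import ReferenceSet, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20170321)


@pytest.fixture
def tiny_transcript():
    # utr5 3 nt, CDS 4 codons, utr3 2 nt
    return TranscriptModel(
        transcript_id="t1", gene_id="g1",
        sequence="AAA" + "ATGGGCTGCTAA" + "TT",
        utr5_len=3, cds_len=12, utr3_len=2,
    )


@pytest.fixture
def tiny_reference(tiny_transcript):
    t2 = TranscriptModel(
        transcript_id="t2", gene_id="g2",
        sequence="CCCC" + "ATGAAACCCGGGTAA" + "GGG",
        utr5_len=4, cds_len=15, utr3_len=3,
    )
    return ReferenceSet([tiny_transcript, t2])


def random_codon_counts(rng, n_codons, total=200):
    """Random nonnegative codon vector with a fixed total."""
    p = rng.dirichlet(np.ones(n_codons))
    return rng.multinomial(total, p)
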