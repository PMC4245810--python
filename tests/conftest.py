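import pytest

from leakyscan.model import TisRecord, TranscriptTisSet


def make_tis_set(
    signals,
    transcript_id="tx1",
    gene_id="g1",
    codons=None,
    positions=None,
    sequence=None,
    is_single_isoform=True,
):
    """Build a TranscriptTisSet from a signal vector with sane defaults."""
    k = len(signals)
    if positions is None:
        positions = [12 * (i + 1) for i in range(k)]
    if codons is None:
        codons = ["ATG"] * k
    tis_list = [
        TisRecord(
            gene_id=gene_id,
            transcript_id=transcript_id,
            position=p,
            codon=c,
            signal=float(s),
        )
        for p, c, s in zip(positions, codons, signals)
    ]
    return TranscriptTisSet(
        transcript_id=transcript_id,
        gene_id=gene_id,
        tis_list=tis_list,
        sequence=sequence,
        is_single_isoform=is_single_isoform,
    )


@pytest.fixture
def three_tis_expected_counts():
    """The three-TIS mRNA with one weak (20%) then two strong (80%)
    starts, at the expected footprint counts under 1000 scanning
    ribosomes: 200, 640, 128, with 32 ribosomes scanning past the last
    TIS undetected."""
    return make_tis_set([200.0, 640.0, 128.0])
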