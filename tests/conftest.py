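import pytest
from hypothesis import settings

from orfmap import ExonChain, GenomeSequence, SearchParams, TranscriptRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def chain(pairs, strand="+", seqid="chr1"):
    return ExonChain.from_pairs(seqid, pairs, strand)


def record(tid, exon_pairs, cds_pairs=None, strand="+", seqid="chr1", gene="g1"):
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gene,
        exons=chain(exon_pairs, strand, seqid),
        cds=chain(cds_pairs, strand, seqid) if cds_pairs else None,
    )


@pytest.fixture
def params():
    return SearchParams()


@pytest.fixture
def genome_factory():
    def make(seq, seqid="chr1"):
        return GenomeSequence({seqid: seq})

    return make
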