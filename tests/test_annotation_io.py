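"""Coordinate semantics, round trips, and spliced-sequence extraction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from orfmap import (
    AnnotationError,
    GenomeSequence,
    GenomicInterval,
    is_valid_orf,
    read_annotation,
    read_genome,
    reverse_complement,
    spliced_sequence,
    write_annotation,
)
from orfmap.annotation_io import cds_phases
from orfmap.simulate import make_locus

from conftest import chain, record


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

GTF_BASIC = (
    'chr1\t.\texon\t101\t200\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n'
)


def test_gtf_coordinates_become_zero_based_half_open(tmp_path):
    path = tmp_path / "a.gtf"
    path.write_text(GTF_BASIC)
    (rec,) = read_annotation(path)
    assert rec.exons.intervals == (GenomicInterval("chr1", 100, 200),)
    assert rec.cds is None  # exons only, no CDS lines


def test_stop_codon_features_merge_into_cds(tmp_path):
    # file spans 11-20 and 31-36 for CDS plus stop_codon 37-39: the merged
    # internal chain is 10-20 plus 30-39, 22 bases — not a codon multiple,
    # so the record is flagged incomplete by the valid-ORF check.
    lines = [
        'chr1\t.\texon\t1\t60\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";',
        'chr1\t.\tCDS\t11\t20\t.\t+\t0\ttranscript_id "t1"; gene_id "g1";',
        'chr1\t.\tCDS\t31\t36\t.\t+\t2\ttranscript_id "t1"; gene_id "g1";',
        'chr1\t.\tstop_codon\t37\t39\t.\t+\t0\ttranscript_id "t1"; gene_id "g1";',
    ]
    path = tmp_path / "a.gtf"
    path.write_text("\n".join(lines) + "\n")
    (rec,) = read_annotation(path)
    assert [(iv.start, iv.end) for iv in rec.cds.intervals] == [
        (10, 20),
        (30, 39),
    ]
    assert rec.cds.total_length == 19  # 10 + 6 CDS bases + 3 stop bases
    genome = GenomeSequence({"chr1": "A" * 60})
    ok, reason = is_valid_orf(rec.cds, genome)
    assert not ok and reason == "length_not_multiple_of_3"


def test_cds_only_record_synthesizes_exons(tmp_path):
    path = tmp_path / "a.gtf"
    path.write_text(
        'chr1\t.\tCDS\t11\t19\t.\t+\t0\ttranscript_id "t1"; gene_id "g1";\n'
    )
    (rec,) = read_annotation(path)
    assert rec.exons == rec.cds


def test_mixed_strand_transcript_rejected(tmp_path):
    path = tmp_path / "a.gtf"
    path.write_text(
        'chr1\t.\texon\t1\t50\t.\t+\t.\ttranscript_id "t1";\n'
        'chr1\t.\texon\t60\t90\t.\t-\t.\ttranscript_id "t1";\n'
    )
    with pytest.raises(AnnotationError, match="mixed strands"):
        read_annotation(path)


def test_malformed_line_names_line_number(tmp_path):
    path = tmp_path / "a.gtf"
    path.write_text(GTF_BASIC + "chr1\tonly-three\tfields\n")
    with pytest.raises(AnnotationError, match="line 2"):
        read_annotation(path)


def test_part_feature_without_transcript_id_rejected(tmp_path):
    path = tmp_path / "a.gff3"
    path.write_text("chr1\t.\tCDS\t11\t19\t.\t+\t0\tID=c1\n")
    with pytest.raises(AnnotationError, match="no transcript/Parent"):
        read_annotation(path)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def test_phase_column_accumulates_five_prime_to_three_prime():
    # first coding piece of 7 bases leaves phase (3 - 7 % 3) % 3 = 2
    cds = chain([(10, 17), (30, 45)])
    assert cds_phases(cds) == [0, 2]
    minus = chain([(10, 17), (30, 44)], "-")  # 5' piece is the right one
    assert cds_phases(minus) == [1, 0]


def test_gtf_splits_stop_codon_and_round_trips(tmp_path):
    rec = record("t1", [(0, 120)], [(9, 30)])  # 21 bases incl. stop
    path = tmp_path / "out.gtf"
    write_annotation([rec], path, "gtf")
    text = path.read_text()
    assert "\tCDS\t10\t27\t" in text  # stop excluded from CDS lines
    assert "\tstop_codon\t28\t30\t" in text
    (back,) = read_annotation(path)
    assert back.cds == rec.cds and back.exons == rec.exons


@pytest.mark.parametrize("fmt", ["gtf", "gff3"])
@pytest.mark.parametrize("seed", [3, 17, 28])
def test_read_write_read_is_coordinate_identical(tmp_path, fmt, seed):
    locus = make_locus(seed, n_isoforms=3)
    records = [locus.reference] + [
        iso for iso in locus.isoforms if iso.cds is not None
    ]
    p1 = tmp_path / f"one.{fmt}"
    p2 = tmp_path / f"two.{fmt}"
    write_annotation(records, p1, fmt)
    first = read_annotation(p1)
    write_annotation(first, p2, fmt)
    second = read_annotation(p2)
    key = lambda rs: [(r.transcript_id, r.exons, r.cds) for r in rs]
    assert key(first) == key(second)
    assert sorted(key(first)) == sorted(key(records))


def test_cds_escaping_exons_rejected():
    with pytest.raises(ValueError, match="escapes"):
        record("t1", [(0, 50)], [(40, 70)])


# ---------------------------------------------------------------------------
# FASTA and spliced sequences
# ---------------------------------------------------------------------------

def test_read_genome_semantics(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">chr1 some description\nacgt\n>chr2\nNNAA\n")
    genome = read_genome(path)
    assert genome.fetch("chr1", 0, 4) == "ACGT"  # uppercased, id split
    assert genome.fetch("chr2", 0, 2) == "NN"
    path.write_text(">chr1\nAC\n>chr1\nGG\n")
    with pytest.raises(AnnotationError, match="duplicate"):
        read_genome(path)
    path.write_text("")
    with pytest.raises(AnnotationError, match="no sequences"):
        read_genome(path)


@pytest.mark.parametrize(
    "pairs,strand,expected",
    [
        ([(0, 3), (6, 9)], "+", "ATGTAA"),
        ([(0, 3), (6, 9)], "-", "TTACAT"),  # reverse complement by hand
        ([(0, 9)], "+", "ATGCCCTAA"),
    ],
)
def test_spliced_sequence_examples(genome_factory, pairs, strand, expected):
    genome = genome_factory("ATGCCCTAA")
    assert spliced_sequence(chain(pairs, strand), genome) == expected


def test_spliced_sequence_out_of_bounds(genome_factory):
    genome = genome_factory("ATGCCCTAA")
    with pytest.raises(IndexError):
        spliced_sequence(chain([(4, 20)]), genome)


@st.composite
def random_chain(draw):
    n = draw(st.integers(1, 5))
    gaps = draw(st.lists(st.integers(1, 10), min_size=n, max_size=n))
    lens = draw(st.lists(st.integers(1, 12), min_size=n, max_size=n))
    strand = draw(st.sampled_from("+-"))
    pairs = []
    pos = draw(st.integers(0, 5))
    for g, ln in zip(gaps, lens):
        pairs.append((pos + g, pos + g + ln))
        pos += g + ln
    return chain(pairs, strand)


@given(random_chain(), st.randoms(use_true_random=False))
def test_spliced_length_and_strand_flip(ch, rnd):
    seq = "".join(rnd.choice("ACGT") for _ in range(ch.span_end + 3))
    genome = GenomeSequence({"chr1": seq})
    s = spliced_sequence(ch, genome)
    assert len(s) == ch.total_length
    flipped = ch.with_strand("-" if ch.strand == "+" else "+")
    assert s == reverse_complement(spliced_sequence(flipped, genome))


@given(random_chain())
def test_tx_genomic_mapping_round_trips(ch):
    for off in range(ch.total_length):
        pos = ch.tx_to_genomic(off)
        assert ch.genomic_to_tx(pos) == off
    # subchain of the full window reproduces the chain
    assert ch.subchain(0, ch.total_length) == ch
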