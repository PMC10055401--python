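"""Candidate generation, start selection, scoring, and the cascade."""

import pytest

from orfmap import (
    GenomeSequence,
    CandidateOrf,
    OrfScore,
    SearchParams,
    annotate,
    enumerate_candidates,
    extend_to_stop,
    frame_of,
    intersect_chains,
    is_valid_orf,
    score_candidate,
    select_best,
    select_start,
    spliced_sequence,
)

from conftest import chain, record


# ---------------------------------------------------------------------------
# interval and frame primitives
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "query,ref,expected",
    [
        ([(0, 100)], [(10, 20), (40, 50)], [(10, 20), (40, 50)]),
        ([(0, 10)], [(50, 60)], []),
        ([(0, 30), (60, 90)], [(20, 70)], [(20, 30), (60, 70)]),
    ],
)
def test_intersect_chains(query, ref, expected):
    got = intersect_chains(chain(query), chain(ref))
    assert [(iv.start, iv.end) for iv in got] == expected


def test_frame_of_tracks_coding_offset_across_junctions():
    # exon1 contributes 2 coding bases; the 4th base (offset 3) opens codon 2
    cds = chain([(10, 12), (20, 30)])
    assert frame_of(cds, 10) == 0
    assert frame_of(cds, 11) == 1
    assert frame_of(cds, 21) == 0  # offset 3 -> frame 0
    assert frame_of(cds, 5) is None
    minus = chain([(10, 12), (20, 30)], "-")
    assert frame_of(minus, 29) == 0  # 5'-most base on '-'


# ---------------------------------------------------------------------------
# extension and start selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,anchor,expected",
    [
        ("ATGAAATAG", 0, 9),
        ("ATGAAA", 0, None),  # transcript ends without a stop
        ("AATGATAGA", 1, None),  # codons ATG ATA GA.: no stop reachable
        ("ATGNNNTAATAG", 0, None),  # N codon breaks the frame
        ("ATGTAGTAA", 0, 6),  # first stop wins
    ],
)
def test_extend_to_stop(seq, anchor, expected):
    assert extend_to_stop(seq, anchor) == expected


def test_select_start_prefers_more_inframe_bases():
    # full reference coverage: the 5'-most ATG yields more in-frame bases
    seq = "ATGATGAAATAG"
    assert select_start(seq, 12, lambda s: 9 - s) == 0


def test_select_start_tie_goes_to_least_novel():
    # coverage begins at offset 6; the upstream ATG adds only novel bases
    seq = "ATG" + "AAA" + "ATG" + "AAA" + "TAG"

    def shared(s):
        return max(0, (12 - max(s, 6)) // 3 * 3)

    assert select_start(seq, 15, shared) == 6


def test_select_start_blocked_by_intervening_stop_and_none_when_no_start():
    seq = "ATG" + "TAA" + "CCC" + "AAA" + "TAG"  # ATG is behind a stop
    assert select_start(seq, 15, lambda s: 1) is None
    assert select_start("CCCCCCTAG", 9, lambda s: 1) is None


def test_select_start_respects_min_orf_length():
    seq = "ATGATGTAG"
    params = SearchParams(min_orf_length=2)
    assert select_start(seq, 9, lambda s: 1, params) == 0  # 2 codons needed


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_score_identical_chain_is_perfect():
    cds = chain([(0, 30)])
    sc = score_candidate(cds, cds)
    assert (sc.ilpi, sc.novel_bases) == (1.0, 0)
    assert sc.il == sc.length == 27


def test_score_out_of_frame_overlap_is_zero():
    assert score_candidate(chain([(0, 30)]), chain([(1, 31)])).il == 0


def test_score_partial_coverage_of_reference():
    # candidate covering codons 1-10 of a 17-codon reference, in frame
    ref = chain([(0, 54)])  # 17 codons + stop
    cand = chain([(0, 33)])  # 10 codons + stop
    sc = score_candidate(cand, ref)
    assert sc.il == 30
    assert sc.ilpi == pytest.approx(30 / 51)
    assert sc.length == 30


def test_score_counts_only_complete_shared_codons():
    # sharing ends mid-codon after 7 bases: only 2 whole codons count
    ref = chain([(0, 54)])
    cand = chain([(0, 7), (100, 126)])
    assert score_candidate(cand, ref).il == 6


def test_score_reference_stop_codon_excluded():
    ref = chain([(0, 30)])
    cand = chain([(0, 30)])
    sc = score_candidate(cand, ref)
    assert sc.il == 27  # the stop codon encodes no residue


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def _cand(tx_start, il, ilpi, length):
    return CandidateOrf(
        cds=chain([(tx_start, tx_start + length + 3)]),
        tx_start=tx_start,
        tx_end=tx_start + length + 3,
        score=OrfScore(il=il, ilpi=ilpi, length=length),
    )


def test_cascade_length_is_third_criterion():
    a = _cand(0, 270, 0.9, 300)
    b = _cand(500, 270, 0.9, 450)
    assert select_best([a, b]) is b


def test_cascade_prefers_more_matching_residues_in_both_modes():
    # 13/17 vs 4/17 matching codons against the same reference
    a = _cand(0, 39, 39 / 51, 60)
    b = _cand(100, 12, 12 / 51, 45)
    assert select_best([a, b], SearchParams()) is a
    assert select_best([a, b], SearchParams(mode="maximize_IL")) is a


def test_cascade_tie_breaks_to_five_prime_most_start():
    a = _cand(30, 27, 0.5, 27)
    b = _cand(0, 27, 0.5, 27)
    assert select_best([a, b]) is b
    assert select_best([]) is None


# ---------------------------------------------------------------------------
# a hand-built locus where the two modes disagree
# ---------------------------------------------------------------------------

def _mode_divergent_fixture():
    seq = (
        "ATG" + "GCT" * 8 + "TAA"          # ORF1 [0,30): matches ref1 fully
        + "ATG" + "GCA" * 18 + "TGA"       # ORF2 [30,90): prefix of ref2
        + "CCC" * 10                        # [90,120) 3' UTR of the query
        + "A" * 80                          # ref2 intron [120,200)
        + "GTT" * 20 + "TAG"                # ref2 3' coding exon [200,263)
        + "C" * 17
    )
    genome = GenomeSequence({"chr1": seq})
    ref1 = record("ref1", [(0, 30)], [(0, 30)])
    ref2 = record("ref2", [(30, 87), (200, 263)], [(30, 87), (200, 263)])
    query = record("q", [(0, 120)])
    return genome, [ref1, ref2], query


def test_modes_select_different_orfs_on_divergent_fixture():
    genome, refs, query = _mode_divergent_fixture()
    for ref in refs:
        assert is_valid_orf(ref.cds, genome)[0]
    ilpi_best = select_best(
        enumerate_candidates(query, refs, genome), SearchParams()
    )
    il_params = SearchParams(mode="maximize_IL")
    il_best = select_best(
        enumerate_candidates(query, refs, genome, il_params), il_params
    )
    # maximizing ILPI keeps the short exact match; maximizing IL accepts
    # novel sequence for more matched bases
    assert [(iv.start, iv.end) for iv in ilpi_best.cds.intervals] == [(0, 30)]
    assert ilpi_best.score.ilpi == 1.0 and ilpi_best.score.il == 27
    assert [(iv.start, iv.end) for iv in il_best.cds.intervals] == [(30, 90)]
    assert il_best.score.il == 57
    assert il_best.best_reference_id == "ref2"


# ---------------------------------------------------------------------------
# candidate generation and the driver
# ---------------------------------------------------------------------------

def test_query_identical_to_reference_yields_reference_orf():
    genome, refs, _ = _mode_divergent_fixture()
    ref1 = refs[0]
    query = record("q", [(0, 30)])
    cands = enumerate_candidates(query, [ref1], genome)
    assert len(cands) == 1
    assert cands[0].cds == ref1.cds
    assert cands[0].score.ilpi == 1.0


def test_query_without_overlap_has_no_candidates():
    genome, refs, _ = _mode_divergent_fixture()
    query = record("q", [(264, 280)])
    assert enumerate_candidates(query, refs, genome) == []


def test_identity_recovery_when_reference_cds_contained():
    # query exons contain the full reference CDS chain -> ILPI 1.0
    genome, refs, query = _mode_divergent_fixture()
    best = select_best(enumerate_candidates(query, [refs[0]], genome))
    assert best.score.ilpi == 1.0


def test_n_codon_interrupting_orf_discards_candidate():
    seq = "ATG" + "GCT" * 3 + "TAA"
    genome_ok = GenomeSequence({"chr1": seq + "C" * 10})
    broken = seq[:6] + "NNN" + seq[9:]
    genome_n = GenomeSequence({"chr1": broken + "C" * 10})
    ref = record("r", [(0, 15)], [(0, 15)])
    query = record("q", [(0, 15)])
    assert len(enumerate_candidates(query, [ref], genome_ok)) == 1
    assert enumerate_candidates(query, [ref], genome_n) == []


def test_annotate_preserves_noncoding_and_attribute_payload():
    genome, refs, query = _mode_divergent_fixture()
    far = record("far", [(300, 340)])
    far.attributes["note"] = "kept"
    out = annotate(refs, [query, far], genome)
    assert out[0].cds is not None
    assert out[1].cds is None and out[1].attributes["note"] == "kept"
    # original query order preserved
    assert [r.transcript_id for r in out] == ["q", "far"]


def test_annotate_drops_invalid_reference_with_warning(caplog):
    genome, refs, query = _mode_divergent_fixture()
    bad = record("bad", [(90, 120)], [(90, 120)])  # CCC... has no start
    import logging

    with caplog.at_level(logging.WARNING, logger="orfmap"):
        out = annotate([bad] + refs, [query], genome)
    assert "dropping reference bad" in caplog.text
    assert out[0].cds is not None


def test_emitted_cds_always_satisfies_valid_orf_definition():
    genome, refs, query = _mode_divergent_fixture()
    for mode in ("maximize_ILPI", "maximize_IL"):
        params = SearchParams(mode=mode)
        out = annotate(refs, [query], genome, params)
        seq = spliced_sequence(out[0].cds, genome)
        assert seq[:3] == "ATG" and seq[-3:] in {"TAA", "TAG", "TGA"}
        assert len(seq) % 3 == 0
        assert is_valid_orf(out[0].cds, genome, params)[0]
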