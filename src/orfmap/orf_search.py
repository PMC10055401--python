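"""Reference-guided ORF search on query transcripts.

The search never aligns sequences.  For each query transcript it
intersects the query exon chain with every overlapping reference CDS
chain, derives the reading frame the reference implies at each shared
region, and extends candidate ORFs along the query transcript: downstream
to the single reachable stop codon and upstream to the start codon that
maximizes the number of reference codons reproduced in frame.

Candidates are ranked by three scores applied in succession:

* IL   (in-frame length) — number of coding bases whose entire codon is
  shared with the reference in the same reading frame, so that query and
  reference code for the same codon at those positions;
* ILPI (in-frame length percent identity) — IL divided by the reference
  coding length (stop codon excluded);
* ORF length (stop codon excluded).

Under the default ``maximize_ILPI`` mode the cascade is ILPI, fewest
novel bases, IL, length; under ``maximize_IL`` it is IL, ILPI, fewest
novel bases, length.  Remaining ties go to the 5'-most transcript-space
start.  Stop codons never count toward IL or the reference length: they
encode no residue.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .annotation_io import (
    ExonChain,
    GenomeSequence,
    GenomicInterval,
    TranscriptRecord,
    spliced_sequence,
)
from .bundling import build_bundles

logger = logging.getLogger("orfmap")

DEFAULT_START_CODONS = frozenset({"ATG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class SearchParams:
    """Tunable parameters of the ORF search.

    mode: 'maximize_ILPI' (default) or 'maximize_IL'.
    min_orf_length: minimum coding length in codons, start included and
    stop excluded.
    """

    mode: str = "maximize_ILPI"
    start_codons: frozenset[str] = DEFAULT_START_CODONS
    stop_codons: frozenset[str] = DEFAULT_STOP_CODONS
    min_orf_length: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("maximize_ILPI", "maximize_IL"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.start_codons or not self.stop_codons:
            raise ValueError("start/stop codon sets must be non-empty")
        if self.start_codons & self.stop_codons:
            raise ValueError("start and stop codon sets must be disjoint")
        if self.min_orf_length < 1:
            raise ValueError("min_orf_length must be >= 1")


@dataclass(frozen=True)
class OrfScore:
    """The (IL, ILPI, length) triple driving selection, plus novel-base count.

    When maximizing ILPI the ranking is ILPI, then fewest novel bases
    (coding bases absent from the reference), then IL, then length: with
    the reference fully reproduced, the search keeps as little novel
    sequence as possible rather than padding the ORF with unsupported
    codons.  When maximizing IL the match count comes first — longer
    ORFs with more novel sequence win if they add matched bases — and
    novel minimization drops behind ILPI.
    """

    il: int
    ilpi: float
    length: int
    novel_bases: int = 0

    def key(self, mode: str) -> tuple:
        if mode == "maximize_IL":
            return (self.il, self.ilpi, -self.novel_bases, self.length)
        return (self.ilpi, -self.novel_bases, self.il, self.length)


@dataclass
class CandidateOrf:
    """One valid ORF on a query transcript (genomic chain includes stop)."""

    cds: ExonChain
    tx_start: int
    tx_end: int
    best_reference_id: str | None = None
    score: OrfScore = field(default_factory=lambda: OrfScore(0, 0.0, 0))


# ---------------------------------------------------------------------------
# Interval and frame primitives
# ---------------------------------------------------------------------------

def intersect_chains(
    query_exons: ExonChain, reference_cds: ExonChain
) -> list[GenomicInterval]:
    """Maximal genomic intervals present in both chains (sorted)."""
    if query_exons.seqid != reference_cds.seqid:
        return []
    out: list[GenomicInterval] = []
    a, b = query_exons.intervals, reference_cds.intervals
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo < hi:
            out.append(GenomicInterval(a[i].seqid, lo, hi))
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return out


def frame_of(reference_cds: ExonChain, genomic_pos: int) -> int | None:
    """Codon position (0/1/2) of a genomic base within a reference CDS.

    The offset is taken 5'->3' in transcript orientation over the full CDS
    chain (stop codon included); None outside the CDS.
    """
    off = reference_cds.genomic_to_tx(genomic_pos)
    return None if off is None else off % 3


def _shared_runs(
    query: ExonChain, reference_cds: ExonChain
) -> list[tuple[int, int, int]]:
    """Shared coding positions as (q_off, r_off, length) runs.

    Each run covers genomic bases present in both chains where the query
    offset and reference offset advance together in transcript
    orientation; reference stop-codon bases are trimmed off.  Runs are
    merged across junctions spliced identically by both chains, so codons
    straddling shared introns stay in one run.
    """
    ref_coding_len = reference_cds.total_length - 3
    if ref_coding_len <= 0:
        return []
    runs: list[tuple[int, int, int]] = []
    for iv in intersect_chains(query, reference_cds):
        if query.strand == "+":
            q0 = query.genomic_to_tx(iv.start)
            r0 = reference_cds.genomic_to_tx(iv.start)
        else:
            q0 = query.genomic_to_tx(iv.end - 1)
            r0 = reference_cds.genomic_to_tx(iv.end - 1)
        length = iv.length
        # trim reference stop-codon bases (highest reference offsets)
        if r0 >= ref_coding_len:
            continue
        length = min(length, ref_coding_len - r0)
        runs.append((q0, r0, length))
    runs.sort()
    merged: list[list[int]] = []
    for q0, r0, ln in runs:
        if merged and merged[-1][0] + merged[-1][2] == q0 and merged[-1][1] + merged[-1][2] == r0:
            merged[-1][2] += ln
        else:
            merged.append([q0, r0, ln])
    return [tuple(m) for m in merged]


def _inframe_codons(
    runs: list[tuple[int, int, int]], frame: int, lo: int, hi: int
) -> int:
    """Bases of complete in-frame shared codons within query window [lo, hi).

    Only runs whose query/reference offsets are phase-compatible with the
    candidate frame contribute; a codon counts only when all three of its
    bases sit inside one run (query and reference code for the same codon).
    """
    total = 0
    for q0, r0, ln in runs:
        # candidate codon boundaries sit at query offsets ≡ frame (mod 3);
        # in-frame sharing needs the reference codon boundary to coincide.
        if (q0 - (r0 % 3)) % 3 != frame % 3:
            continue
        a = max(q0, lo)
        b = min(q0 + ln, hi)
        if b <= a:
            continue
        c0 = a + ((frame - a) % 3)
        if c0 + 3 > b:
            continue
        total += 3 * ((b - c0) // 3)
    return total


# ---------------------------------------------------------------------------
# ORF extension along the query transcript
# ---------------------------------------------------------------------------

def _codon_kind(seq: str, pos: int, params: SearchParams) -> str:
    codon = seq[pos : pos + 3]
    if len(codon) < 3:
        return "partial"
    if "N" in codon:
        return "n"
    if codon in params.stop_codons:
        return "stop"
    if codon in params.start_codons:
        return "start"
    return "other"


def _scan_frame(
    query_tx_seq: str, frame_anchor: int, params: SearchParams
) -> tuple[str, int]:
    """Scan codons 3' from the anchor until a stop, an N codon, or the end.

    Returns ('stop', end_offset_after_stop), ('n', offset_after_n_codon)
    or ('end', sequence_length).
    """
    n = len(query_tx_seq)
    for pos in range(frame_anchor, n - 2, 3):
        kind = _codon_kind(query_tx_seq, pos, params)
        if kind == "stop":
            return "stop", pos + 3
        if kind == "n":
            return "n", pos + 3
    return "end", n


def extend_to_stop(
    query_tx_seq: str, frame_anchor: int, params: SearchParams | None = None
) -> int | None:
    """End offset (exclusive) of the first stop codon 3' of the anchor.

    Scans in steps of 3 from the anchor; returns None when the transcript
    ends without a stop, or when a codon containing N interrupts the
    reading frame before one is reached (an N codon breaks the ORF).
    """
    params = params or SearchParams()
    if not 0 <= frame_anchor < len(query_tx_seq):
        raise IndexError("anchor outside transcript")
    kind, end = _scan_frame(query_tx_seq, frame_anchor, params)
    return end if kind == "stop" else None


def select_start(
    query_tx_seq: str,
    stop_end: int,
    inframe_shared,
    params: SearchParams | None = None,
) -> int | None:
    """Optimal start-codon offset for the ORF ending at ``stop_end``.

    Valid starts s satisfy: s ≡ stop_end (mod 3), a start codon at s, no
    stop or N codon between s and the final stop, and coding length
    >= min_orf_length codons.  Among them the winner maximizes the
    in-frame bases shared with the reference (``inframe_shared(s)``),
    breaking ties by minimizing bases not shared in frame — i.e. the
    shortest, least-novel extension — then taking the 5'-most offset.
    Returns None when no valid start exists.
    """
    params = params or SearchParams()
    best: tuple | None = None
    best_s: int | None = None
    s = stop_end - 3 - 3 * params.min_orf_length
    while s >= 0:
        kind = _codon_kind(query_tx_seq, s, params)
        if kind in ("stop", "n"):
            break  # intervening breaker: nothing further upstream is valid
        if kind == "start":
            il = inframe_shared(s)
            length = stop_end - 3 - s
            key = (il, -(length - il), -length)  # max IL, min novel, min len
            if best is None or key > best:
                best, best_s = key, s
        s -= 3
    return best_s


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _chain_overlap_bases(a: ExonChain, b: ExonChain) -> int:
    return sum(iv.length for iv in intersect_chains(a, b))


def score_candidate(
    candidate_cds: ExonChain, reference_cds: ExonChain
) -> OrfScore:
    """Score a candidate ORF chain against one reference CDS chain.

    Both chains include their stop codons; stop bases count toward
    neither IL, ILPI denominator, nor length.
    """
    cand_len = candidate_cds.total_length - 3
    ref_len = reference_cds.total_length - 3
    if cand_len <= 0 or ref_len <= 0:
        return OrfScore(0, 0.0, max(cand_len, 0), 0)
    cand_coding = candidate_cds.subchain(0, cand_len)
    runs = _shared_runs(cand_coding, reference_cds)
    il = _inframe_codons(runs, 0, 0, cand_len)
    ilpi = il / ref_len
    novel = cand_len - _chain_overlap_bases(cand_coding, reference_cds)
    return OrfScore(il=il, ilpi=ilpi, length=cand_len, novel_bases=novel)


def _better(a: tuple, b: tuple | None) -> bool:
    return b is None or a > b


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def enumerate_candidates(
    query: TranscriptRecord,
    references: list[TranscriptRecord],
    genome: GenomeSequence,
    params: SearchParams | None = None,
) -> list[CandidateOrf]:
    """All reference-anchored candidate ORFs on one query transcript.

    For every reference CDS and reading frame it implies on the query,
    candidate ORFs are seeded at successive shared in-frame regions,
    completed by stop extension and start selection, and scored against
    every reference (the best-scoring reference is recorded).  Candidates
    with identical genomic chains are deduplicated; candidates sharing no
    in-frame codon with any reference are dropped — the search is
    reference-guided by construction.
    """
    params = params or SearchParams()
    if query.seqid not in genome:
        raise KeyError(f"sequence {query.seqid!r} not in genome")
    seq = spliced_sequence(query.exons, genome)
    n = len(seq)

    refs = [r for r in references if r.cds is not None and r.strand == query.strand]
    seen: dict[tuple[int, int], CandidateOrf] = {}

    for ref in refs:
        runs = _shared_runs(query.exons, ref.cds)
        if not runs:
            continue
        # group runs by the query-frame the reference implies
        by_frame: dict[int, list[tuple[int, int, int]]] = {}
        for q0, r0, ln in runs:
            frame = (q0 - (r0 % 3)) % 3
            by_frame.setdefault(frame, []).append((q0, r0, ln))
        for frame, fruns in by_frame.items():
            fruns.sort()

            def il_of(s: int, e: int, fruns=fruns, frame=frame) -> int:
                return _inframe_codons(fruns, frame, s, e)

            def next_shared(offset: int, fruns=fruns) -> int | None:
                for q0, _r0, ln in fruns:
                    if q0 + ln > offset:
                        return max(q0, offset)
                return None

            pos: int | None = fruns[0][0]
            while pos is not None:
                anchor = pos - ((pos - frame) % 3)
                if anchor < 0:
                    anchor += 3
                if anchor >= n:
                    break
                kind, end = _scan_frame(seq, anchor, params)
                if kind == "end":
                    break  # no stop reachable in this frame from here on
                if kind == "n":
                    pos = next_shared(end)
                    continue
                stop_end = end
                s = select_start(
                    seq,
                    stop_end,
                    lambda s, stop_end=stop_end, il_of=il_of: il_of(
                        s, stop_end - 3
                    ),
                    params,
                )
                if s is not None and il_of(s, stop_end - 3) > 0:
                    if (s, stop_end) not in seen:
                        seen[(s, stop_end)] = CandidateOrf(
                            cds=query.exons.subchain(s, stop_end),
                            tx_start=s,
                            tx_end=stop_end,
                        )
                # advance to the next shared in-frame region past this stop
                pos = next_shared(stop_end)

    candidates = list(seen.values())
    # score every candidate against every reference; keep the best
    for cand in candidates:
        best_key = None
        for ref in refs:
            sc = score_candidate(cand.cds, ref.cds)
            key = sc.key(params.mode)
            if _better(key, best_key):
                best_key = key
                cand.score = sc
                cand.best_reference_id = ref.transcript_id
    candidates = [c for c in candidates if c.score.il > 0]
    candidates.sort(key=lambda c: c.tx_start)
    return candidates


def select_best(
    candidates: list[CandidateOrf], params: SearchParams | None = None
) -> CandidateOrf | None:
    """Apply the score cascade; ties go to the 5'-most transcript start."""
    params = params or SearchParams()
    best = None
    best_key = None
    for cand in candidates:
        key = (cand.score.key(params.mode), -cand.tx_start)
        if _better(key, best_key):
            best, best_key = cand, key
    return best


# ---------------------------------------------------------------------------
# Top-level driver
# ---------------------------------------------------------------------------

def is_valid_orf(
    cds: ExonChain, genome: GenomeSequence, params: SearchParams | None = None
) -> tuple[bool, str]:
    """Check the valid-ORF definition on a CDS chain (stop included)."""
    params = params or SearchParams()
    seq = spliced_sequence(cds, genome)
    if len(seq) % 3 != 0:
        return False, "length_not_multiple_of_3"
    if len(seq) < 3 * (params.min_orf_length + 1):
        return False, "too_short"
    if seq[:3] not in params.start_codons:
        return False, "no_start"
    if seq[-3:] not in params.stop_codons:
        return False, "no_stop"
    for pos in range(3, len(seq) - 3, 3):
        codon = seq[pos : pos + 3]
        if codon in params.stop_codons:
            return False, "internal_stop"
        if "N" in codon:
            return False, "ambiguous_base"
    return True, "ok"


def _annotate_bundle(bundle, genome, params):
    out: dict[str, list[CandidateOrf]] = {}
    for query in bundle.queries:
        out[query.transcript_id] = enumerate_candidates(
            query, bundle.references, genome, params
        )
    return out


def annotate(
    references: list[TranscriptRecord],
    queries: list[TranscriptRecord],
    genome: GenomeSequence,
    params: SearchParams | None = None,
    group_by_gene: bool = False,
    threads: int = 1,
) -> list[TranscriptRecord]:
    """Assign the best reference-guided ORF to every query transcript.

    References whose CDS fails the valid-ORF check are dropped with a
    warning.  Queries overlapping no reference CDS, or admitting no valid
    candidate, are returned without a CDS.  Output order follows the input
    query order and is independent of threading.
    """
    params = params or SearchParams()
    usable = []
    for ref in references:
        if ref.cds is None:
            continue
        if ref.seqid not in genome:
            raise KeyError(f"sequence {ref.seqid!r} not in genome")
        ok, reason = is_valid_orf(ref.cds, genome, params)
        if ok:
            usable.append(ref)
        else:
            logger.warning(
                "dropping reference %s: %s", ref.transcript_id, reason
            )
    bundles, _unplaced = build_bundles(usable, queries, group_by_gene)

    if threads > 1 and len(bundles) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            per_bundle = list(
                pool.map(lambda b: _annotate_bundle(b, genome, params), bundles)
            )
    else:
        per_bundle = [_annotate_bundle(b, genome, params) for b in bundles]

    # union candidates across bundles (a readthrough query may join several)
    by_query: dict[str, list[CandidateOrf]] = {}
    for result in per_bundle:
        for tid, cands in result.items():
            by_query.setdefault(tid, []).extend(cands)

    out: list[TranscriptRecord] = []
    for query in queries:
        rec = query.copy()
        cands = by_query.get(query.transcript_id, [])
        # deduplicate identical chains, keeping the better score
        uniq: dict[tuple, CandidateOrf] = {}
        for c in cands:
            key = (c.tx_start, c.tx_end)
            prev = uniq.get(key)
            if prev is None or _better(
                c.score.key(params.mode), prev.score.key(params.mode)
            ):
                uniq[key] = c
        best = select_best(list(uniq.values()), params)
        rec.cds = best.cds if best is not None else None
        if best is not None:
            rec.attributes = dict(rec.attributes)
        out.append(rec)
    return out
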