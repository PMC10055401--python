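"""Evaluation machinery: ORF-vs-ORF classification, protein identity,
and reference-set cleaning.

Classification compares three annotation sets per transcript — the newly
annotated set, the original annotation it replaces, and a canonical set
(one designated ORF per gene, matched by CDS-span overlap on the same
strand) — and assigns each transcript one category based on exact genomic
CDS-chain equality.  Chain equality implies protein equality, never the
reverse, so the categories are conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .annotation_io import (
    ExonChain,
    GenomeSequence,
    TranscriptRecord,
    spliced_sequence,
)
from .orf_search import SearchParams, is_valid_orf, score_candidate

logger = logging.getLogger("orfmap")

CATEGORIES = (
    "same_as_reference",
    "differs_matches_canonical",
    "differs_reference_matches_canonical",
    "no_reference_orf_found_matches_canonical",
    "no_reference_orf_found_differs",
    "other",
)


@dataclass
class OrfComparison:
    query_id: str
    category: str
    ilpi_vs_canonical: float | None = None
    identity_vs_canonical: float | None = None


@dataclass(frozen=True)
class AlignmentResult:
    percent_identity: float
    score: int
    aligned_length: int


def translate(cds_seq: str) -> str:
    """Standard-code translation of a CDS; trailing stop dropped.

    Codons containing ambiguous bases translate to X.  Raises ValueError
    on internal stop codons or a length that is not a multiple of 3.
    """
    if not cds_seq:
        raise ValueError("empty CDS sequence")
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    aa = str(Seq(cds_seq.upper()).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon in CDS")
    return aa


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner(mode="local")
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        _ALIGNER = aligner
    return _ALIGNER


def protein_identity(a: str, b: str) -> AlignmentResult:
    """Smith-Waterman local alignment identity between two proteins.

    BLOSUM62 with affine gaps (open 10, extend 1); percent identity is
    matches over aligned columns, gap columns included.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches + counts.gaps
    pid = counts.identities / aligned if aligned else 0.0
    return AlignmentResult(
        percent_identity=pid,
        score=int(aln.score),
        aligned_length=int(aligned),
    )


# ---------------------------------------------------------------------------
# Reference cleaning
# ---------------------------------------------------------------------------

def _chains_overlap(a: ExonChain, b: ExonChain) -> bool:
    if a.seqid != b.seqid:
        return False
    i = j = 0
    while i < len(a.intervals) and j < len(b.intervals):
        x, y = a.intervals[i], b.intervals[j]
        if x.start < y.end and y.start < x.end:
            return True
        if x.end < y.end:
            i += 1
        else:
            j += 1
    return False


def clean_reference(
    records: list[TranscriptRecord],
    genome: GenomeSequence,
    params: SearchParams | None = None,
) -> tuple[list[TranscriptRecord], list[tuple[TranscriptRecord, str]]]:
    """Filter a reference set down to well-formed, unambiguous ORFs.

    Removes coding transcripts whose spliced CDS fails the valid-ORF
    check, and both members of every pair of genomically overlapping CDS
    chains labeled with different gene ids (likely curation exceptions or
    annotation errors).  Non-coding records pass through untouched.
    """
    params = params or SearchParams()
    kept: list[TranscriptRecord] = []
    removed: list[tuple[TranscriptRecord, str]] = []
    valid: list[TranscriptRecord] = []
    for rec in records:
        if rec.cds is None:
            kept.append(rec)
            continue
        ok, reason = is_valid_orf(rec.cds, genome, params)
        if ok:
            valid.append(rec)
        else:
            removed.append((rec, reason))
            logger.info("removed %s: %s", rec.transcript_id, reason)

    # cross-gene overlapping-ORF filter (base-level chain overlap)
    flagged: set[str] = set()
    by_loc = sorted(valid, key=lambda r: (r.seqid, r.cds.span_start))
    for i, a in enumerate(by_loc):
        for b in by_loc[i + 1 :]:
            if b.seqid != a.seqid or b.cds.span_start >= a.cds.span_end:
                break
            if a.gene_id != b.gene_id and _chains_overlap(a.cds, b.cds):
                flagged.add(a.transcript_id)
                flagged.add(b.transcript_id)
    for rec in valid:
        if rec.transcript_id in flagged:
            removed.append((rec, "overlapping_gene"))
            logger.info("removed %s: overlapping_gene", rec.transcript_id)
        else:
            kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# Classification against original and canonical annotations
# ---------------------------------------------------------------------------

def _chain_key(chain: ExonChain | None):
    if chain is None:
        return None
    return (
        chain.seqid,
        chain.strand,
        tuple((iv.start, iv.end) for iv in chain.intervals),
    )


def _match_canonical(
    record: TranscriptRecord, canonical: list[TranscriptRecord]
) -> TranscriptRecord | None:
    """Canonical record with the largest CDS-span overlap, same strand."""
    span = (
        (record.cds.span_start, record.cds.span_end)
        if record.cds is not None
        else (record.exons.span_start, record.exons.span_end)
    )
    best = None
    best_ov = 0
    for can in canonical:
        if can.cds is None or can.seqid != record.seqid:
            continue
        if can.strand != record.strand:
            continue
        ov = min(span[1], can.cds.span_end) - max(span[0], can.cds.span_start)
        if ov > best_ov:
            best, best_ov = can, ov
    return best


def classify(
    annotated: list[TranscriptRecord],
    original: list[TranscriptRecord],
    canonical: list[TranscriptRecord],
    genome: GenomeSequence | None = None,
) -> tuple[list[OrfComparison], dict[str, int]]:
    """Categorize each annotated transcript against its original ORF and
    the canonical ORF at its locus.

    Passing a genome additionally computes Smith-Waterman protein percent
    identity against the canonical ORF.  Returns per-transcript results
    and category counts.
    """
    orig_by_id = {r.transcript_id: r for r in original}
    results: list[OrfComparison] = []
    counts = {c: 0 for c in CATEGORIES}
    for rec in annotated:
        orig = orig_by_id.get(rec.transcript_id)
        if orig is None:
            raise KeyError(
                f"{rec.transcript_id} present in annotated set but not in "
                "the original annotation"
            )
        can = _match_canonical(rec, canonical)
        new_key = _chain_key(rec.cds)
        old_key = _chain_key(orig.cds)
        can_key = _chain_key(can.cds) if can is not None else None

        if old_key is not None:
            if new_key == old_key:
                category = "same_as_reference"
            elif new_key is not None and new_key == can_key:
                category = "differs_matches_canonical"
            elif old_key == can_key:
                category = "differs_reference_matches_canonical"
            else:
                category = "other"
        else:
            if new_key is not None and new_key == can_key:
                category = "no_reference_orf_found_matches_canonical"
            elif new_key is not None:
                category = "no_reference_orf_found_differs"
            else:
                category = "other"

        ilpi = None
        identity = None
        if rec.cds is not None and can is not None and can.cds is not None:
            ilpi = score_candidate(rec.cds, can.cds).ilpi
            if genome is not None:
                try:
                    pa = translate(spliced_sequence(rec.cds, genome))
                    pb = translate(spliced_sequence(can.cds, genome))
                    identity = protein_identity(pa, pb).percent_identity
                except ValueError:
                    identity = None
        counts[category] += 1
        results.append(
            OrfComparison(
                query_id=rec.transcript_id,
                category=category,
                ilpi_vs_canonical=ilpi,
                identity_vs_canonical=identity,
            )
        )
    return results, counts
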