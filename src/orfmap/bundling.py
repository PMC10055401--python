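"""Grouping of reference CDS chains and query transcripts into bundles.

A bundle is one connected component of reference CDS chains under genomic
span overlap, together with every query transcript whose exon span
overlaps at least one of those CDS spans on the same strand.  Bundles are
independent units of work: the ORF search never compares transcripts
across bundles, so they can be processed in any order or in parallel.

Bundles are strand-specific — reading frames are undefined across strands
— and overlap is judged on genomic spans (first start to last end) of the
CDS chains; base-level exon intersection happens later in the ORF search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import TranscriptRecord


@dataclass
class Bundle:
    """Overlapping reference CDS chains plus the queries that touch them."""

    seqid: str
    strand: str
    references: list[TranscriptRecord] = field(default_factory=list)
    queries: list[TranscriptRecord] = field(default_factory=list)
    gene_id: str | None = None  # set when grouping by gene id

    @property
    def span(self) -> tuple[int, int]:
        start = min(r.cds.span_start for r in self.references)
        end = max(r.cds.span_end for r in self.references)
        return start, end


def build_bundles(
    references: list[TranscriptRecord],
    queries: list[TranscriptRecord],
    group_by_gene: bool = False,
) -> tuple[list[Bundle], list[TranscriptRecord]]:
    """Sweep-line bundling of references and queries.

    References (which must carry CDS chains) are grouped by overlapping
    CDS spans in a single left-to-right sweep per (seqid, strand) — and
    per gene_id when ``group_by_gene`` is set, so bundles never mix gene
    ids.  Each query attaches to every bundle containing a reference
    whose CDS span overlaps the query exon span on the same strand.
    Queries overlapping no reference CDS span are returned unplaced.
    """
    for ref in references:
        if ref.cds is None:
            raise ValueError(
                f"reference {ref.transcript_id} has no CDS chain"
            )

    def ref_group(r: TranscriptRecord):
        base = (r.seqid, r.strand)
        return base + ((r.gene_id,) if group_by_gene else ())

    grouped: dict[tuple, list[TranscriptRecord]] = {}
    for ref in references:
        grouped.setdefault(ref_group(ref), []).append(ref)

    bundles: list[Bundle] = []
    for key in sorted(grouped):
        refs = sorted(
            grouped[key], key=lambda r: (r.cds.span_start, r.cds.span_end)
        )
        open_bundle: Bundle | None = None
        open_end = -1
        for ref in refs:
            s, e = ref.cds.span_start, ref.cds.span_end
            if open_bundle is not None and s < open_end:
                open_bundle.references.append(ref)
                open_end = max(open_end, e)
            else:
                open_bundle = Bundle(
                    seqid=ref.seqid,
                    strand=ref.strand,
                    references=[ref],
                    gene_id=ref.gene_id if group_by_gene else None,
                )
                bundles.append(open_bundle)
                open_end = e
    bundles.sort(key=lambda b: (b.seqid, b.strand, b.span[0], b.span[1]))

    # attach queries: sweep per (seqid, strand) over bundle reference spans
    by_strand: dict[tuple[str, str], list[Bundle]] = {}
    for b in bundles:
        by_strand.setdefault((b.seqid, b.strand), []).append(b)

    placed_ids: set[str] = set()
    unplaced: list[TranscriptRecord] = []
    for query in queries:
        hits = []
        for b in by_strand.get((query.seqid, query.strand), []):
            qs, qe = query.exons.span_start, query.exons.span_end
            bs, be = b.span
            if qs >= be or bs >= qe:
                continue
            if any(
                qs < r.cds.span_end and r.cds.span_start < qe
                for r in b.references
            ):
                hits.append(b)
        if hits:
            for b in hits:
                b.queries.append(query)
            placed_ids.add(query.transcript_id)
        else:
            unplaced.append(query)
    return bundles, unplaced
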