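"""Synthetic gene loci with known ORF ground truth, and a brute-force oracle.

The generator builds a random multi-exon protein-coding locus on a random
strand, then derives query isoforms by applying one splicing event each
(exon skipping, alternative first exon, alternative 3' splice site, or
intron retention).  The canonical coding sequence is embedded with a
guaranteed valid start and stop; everything else — UTRs, introns,
intergenic background — is uniform random nucleotides, so spurious ATGs
and stop codons occur at natural random-sequence density.  Real splice
site motifs, codon usage bias and expression levels are deliberately not
modeled.

``oracle_best_orf`` is an independent verifier: it enumerates every valid
ORF in the spliced query sequence by direct codon scanning — cubic-
tolerant, no interval machinery — scores each against every reference,
and applies the same selection semantics as the search: per stop, the
start that maximizes in-frame sharing with a reference (ties to the
least-novel, then 5'-most start); across stops, the mode's score cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_io import (
    ExonChain,
    GenomeSequence,
    TranscriptRecord,
    spliced_sequence,
)
from .orf_search import CandidateOrf, SearchParams, score_candidate

SPLICE_EVENTS = frozenset(
    {"exon_skip", "alt_first_exon", "alt_3prime", "intron_retention"}
)

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


class FixtureError(RuntimeError):
    """Raised when no feasible locus can be generated."""


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _enumerate_valid_orfs(
    seq: str, params: SearchParams
) -> list[tuple[int, int]]:
    """All (start, stop_end) pairs forming valid ORFs in a spliced sequence.

    A valid ORF begins with a start codon, ends with the first in-frame
    stop codon, contains no internal stop and no codon with an ambiguous
    base, and holds at least ``min_orf_length`` coding codons.
    """
    orfs: list[tuple[int, int]] = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                starts = []  # ORFs across an ambiguous codon are broken
                continue
            if codon in params.stop_codons:
                for s in starts:
                    if (pos - s) // 3 >= params.min_orf_length:
                        orfs.append((s, pos + 3))
                starts = []
                continue
            if codon in params.start_codons:
                starts.append(pos)
    return orfs


def oracle_best_orf(
    query: TranscriptRecord,
    references: list[TranscriptRecord],
    genome: GenomeSequence,
    params: SearchParams | None = None,
) -> CandidateOrf | None:
    """Independent exhaustive search for the best reference-guided ORF."""
    params = params or SearchParams()
    seq = spliced_sequence(query.exons, genome)
    refs = [
        r
        for r in references
        if r.cds is not None
        and r.strand == query.strand
        and r.seqid == query.seqid
    ]
    if not refs:
        return None

    orfs = _enumerate_valid_orfs(seq, params)
    if not orfs:
        return None
    scored: dict[tuple[int, int], tuple] = {}
    chains: dict[tuple[int, int], ExonChain] = {}
    per_ref: dict[tuple[int, int], list[tuple[int, int, str, object]]] = {}
    for s, e in orfs:
        chain = query.exons.subchain(s, e)
        chains[(s, e)] = chain
        for ref in refs:
            sc = score_candidate(chain, ref.cds)
            per_ref.setdefault((s, e), []).append(
                (sc.il, s, ref.transcript_id, sc)
            )

    # Per (reference, stop): keep only the start that maximizes in-frame
    # sharing with that reference, ties to the shortest ORF.  This mirrors
    # the optimal-start rule; other starts are never candidates.
    keep: set[tuple[int, int]] = set()
    by_stop: dict[int, list[tuple[int, int]]] = {}
    for s, e in orfs:
        by_stop.setdefault(e, []).append((s, e))
    for e, group in by_stop.items():
        for ref in refs:
            best = None
            best_key = None
            for s, _e in group:
                sc = next(
                    x[3]
                    for x in per_ref[(s, e)]
                    if x[2] == ref.transcript_id
                )
                if sc.il <= 0:
                    continue
                key = (sc.il, s)  # max IL, then 3'-most (shortest) start
                if best_key is None or key > best_key:
                    best, best_key = (s, e), key
            if best is not None:
                keep.add(best)

    best_cand: CandidateOrf | None = None
    best_key = None
    for s, e in sorted(keep):
        ref_best = None
        ref_best_key = None
        for _il, _s, rid, sc in per_ref[(s, e)]:
            key = sc.key(params.mode)
            if ref_best_key is None or key > ref_best_key:
                ref_best, ref_best_key = (rid, sc), key
        rid, sc = ref_best
        cand_key = (sc.key(params.mode), -s)
        if best_key is None or cand_key > best_key:
            best_cand = CandidateOrf(
                cds=chains[(s, e)],
                tx_start=s,
                tx_end=e,
                best_reference_id=rid,
                score=sc,
            )
            best_key = cand_key
    return best_cand


# ---------------------------------------------------------------------------
# Locus generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 1) random non-stop codons + a random stop."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


@dataclass
class Locus:
    """A generated locus: genome, canonical reference, query isoforms."""

    genome: GenomeSequence
    reference: TranscriptRecord
    isoforms: list[TranscriptRecord]
    seqid: str
    strand: str


def _flip(pairs, length):
    return [(length - e, length - s) for s, e in pairs]


def make_locus(
    seed: int,
    n_isoforms: int = 3,
    splice_events: frozenset[str] | set[str] = SPLICE_EVENTS,
    params: SearchParams | None = None,
) -> Locus:
    """Generate one random locus with ground-truth ORFs on every isoform.

    The canonical gene has 3-6 exons, each contributing 3-30 codons of a
    single embedded ORF, flanked by random UTRs and introns inside a
    3-10 kb genome.  Each isoform applies one event sampled from
    ``splice_events`` (empty set: isoforms are copies of the canonical
    transcript); its true best ORF is computed by the brute-force oracle
    and stored as its CDS.  Deterministic in ``seed``.
    """
    if n_isoforms < 1:
        raise ValueError("n_isoforms must be >= 1")
    bad = set(splice_events) - SPLICE_EVENTS
    if bad:
        raise ValueError(f"unknown splice events: {sorted(bad)}")
    params = params or SearchParams()
    rng = np.random.default_rng(seed)
    seqid = f"locus{seed}"

    for _attempt in range(50):
        n_exons = int(rng.integers(3, 7))
        codons_per_exon = rng.integers(3, 31, size=n_exons)
        coding = _random_coding(rng, int(codons_per_exon.sum()))
        utr5 = int(rng.integers(30, 300))
        utr3 = int(rng.integers(30, 300))
        # split transcript sequence into exon pieces at arbitrary bases so
        # splice junctions fall at all three codon phases
        tx_seq = _random_seq(rng, utr5) + coding + _random_seq(rng, utr3)
        coding_start, coding_end = utr5, utr5 + len(coding)
        cuts = [0]
        exon_lens = []
        remaining = len(tx_seq)
        base_len = remaining // n_exons
        for i in range(n_exons - 1):
            jitter = int(rng.integers(-base_len // 3, base_len // 3 + 1))
            exon_lens.append(max(20, base_len + jitter))
        exon_lens.append(remaining - sum(exon_lens))
        if exon_lens[-1] < 20:
            continue
        for ln in exon_lens:
            cuts.append(cuts[-1] + ln)

        introns = rng.integers(60, 500, size=n_exons - 1)
        upstream = int(rng.integers(150, 600))
        downstream = int(rng.integers(150, 600))

        exon_pairs = []
        gpos = upstream
        for i in range(n_exons):
            exon_pairs.append((gpos, gpos + exon_lens[i]))
            gpos += exon_lens[i]
            if i < n_exons - 1:
                gpos += int(introns[i])
        glen = gpos + downstream
        if not 3000 <= glen <= 10000:
            # pad or retry; padding downstream keeps the locus intact
            if glen < 3000:
                downstream += 3000 - glen
                glen = 3000
            else:
                continue

        # paint the genome: random background, transcript pieces on exons
        gseq = list(_random_seq(rng, glen))
        for (gs, ge), (ts, te) in zip(
            exon_pairs, zip(cuts[:-1], cuts[1:])
        ):
            gseq[gs:ge] = tx_seq[ts:te]
        gseq = "".join(gseq)

        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            gseq = gseq.translate(
                str.maketrans("ACGTN", "TGCAN")
            )[::-1]
            exon_pairs = sorted(_flip(exon_pairs, glen))

        genome = GenomeSequence({seqid: gseq})
        exons = ExonChain.from_pairs(seqid, exon_pairs, strand)
        # CDS occupies transcript window [coding_start, coding_end)
        cds = exons.subchain(coding_start, coding_end)
        reference = TranscriptRecord(
            transcript_id=f"{seqid}.ref",
            gene_id=f"{seqid}.g",
            exons=exons,
            cds=cds,
        )
        if spliced_sequence(cds, genome)[:3] != "ATG":
            raise AssertionError("embedded ORF lost its start codon")

        isoforms = _make_isoforms(
            rng, reference, genome, n_isoforms, frozenset(splice_events),
            params,
        )
        if isoforms is None:
            continue
        return Locus(
            genome=genome,
            reference=reference,
            isoforms=isoforms,
            seqid=seqid,
            strand=strand,
        )
    raise FixtureError(f"could not generate a feasible locus for seed {seed}")


def _make_isoforms(rng, reference, genome, n_isoforms, events, params):
    exons = reference.exons
    glen = genome.length(exons.seqid)
    ivs = list(exons.intervals)
    isoforms = []
    for i in range(n_isoforms):
        if not events:
            iso_exons = exons
        else:
            iso_exons = None
            for _retry in range(20):
                event = sorted(events)[rng.integers(0, len(events))]
                iso_exons = _apply_event(rng, ivs, exons, event, glen)
                if iso_exons is not None and iso_exons.total_length >= 200:
                    break
                iso_exons = None
            if iso_exons is None:
                return None
        rec = TranscriptRecord(
            transcript_id=f"{reference.transcript_id}.iso{i}",
            gene_id=reference.gene_id,
            exons=iso_exons,
            cds=None,
        )
        truth = oracle_best_orf(rec, [reference], genome, params)
        rec.cds = truth.cds if truth is not None else None
        isoforms.append(rec)
    return isoforms


def _apply_event(rng, ivs, exons, event, glen):
    seqid, strand = exons.seqid, exons.strand
    pairs = [(iv.start, iv.end) for iv in ivs]
    # transcript orientation: index 0 is 5'-most
    tx_pairs = pairs if strand == "+" else pairs[::-1]
    n = len(tx_pairs)
    try:
        if event == "exon_skip":
            if n < 3:
                return None
            k = int(rng.integers(1, n - 1))
            kept = tx_pairs[:k] + tx_pairs[k + 1 :]
            return ExonChain.from_pairs(seqid, kept, strand)
        if event == "alt_first_exon":
            first = tx_pairs[0]
            second = tx_pairs[1]
            ln = int(rng.integers(60, 200))
            if strand == "+":
                hi = first[0] - 10  # stay upstream of the original exon
                if hi - ln <= 5:
                    return None
                start = int(rng.integers(5, hi - ln))
                new_first = (start, start + ln)
            else:
                lo = first[1] + 10
                if lo + 5 + ln > glen - 2:
                    return None
                new_first = (lo + 5, lo + 5 + ln)
            kept = [new_first] + tx_pairs[1:]
            return ExonChain.from_pairs(seqid, kept, strand)
        if event == "alt_3prime":
            if n < 2:
                return None
            k = int(rng.integers(1, n))  # a non-first exon in tx order
            s, e = tx_pairs[k]
            delta = int(rng.integers(1, 31)) * (
                1 if rng.integers(0, 2) else -1
            )
            if strand == "+":
                s2 = s - delta  # +delta extends into the intron
                prev_end = tx_pairs[k - 1][1]
                if not prev_end + 2 <= s2 < e - 10:
                    return None
                new = (s2, e)
            else:
                e2 = e + delta
                prev_start = tx_pairs[k - 1][0]
                if not s + 10 < e2 <= prev_start - 2:
                    return None
                new = (s, e2)
            kept = tx_pairs[:k] + [new] + tx_pairs[k + 1 :]
            return ExonChain.from_pairs(seqid, kept, strand)
        if event == "intron_retention":
            if n < 2:
                return None
            k = int(rng.integers(0, n - 1))
            a, b = tx_pairs[k], tx_pairs[k + 1]
            lo, hi = min(a[0], b[0]), max(a[1], b[1])
            kept = tx_pairs[:k] + [(lo, hi)] + tx_pairs[k + 2 :]
            return ExonChain.from_pairs(seqid, kept, strand)
    except ValueError:
        return None
    return None


def make_diverged_pair(
    seed: int, shared_fraction: float, divergence: float = 0.5
) -> tuple[GenomeSequence, TranscriptRecord, ExonChain]:
    """A reference ORF and a query ORF sharing a controlled codon fraction.

    The query ORF reuses the first ``shared_fraction`` of the reference
    codons genomically (in frame) and continues through a diverged copy
    of the remainder placed elsewhere in the genome, in which each codon
    mutates with probability ``divergence``.  This emulates a pair of
    homologous isoform proteins whose in-frame genomic sharing (hence
    ILPI) is known by construction while the rest stays alignable.
    Returns (genome, reference record, query ORF chain).
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    L = int(rng.integers(40, 100))
    k = int(round(shared_fraction * L))
    coding = _random_coding(rng, L)  # stop included
    codons = [coding[i : i + 3] for i in range(0, 3 * L, 3)]
    diverged = []
    for i in range(k, L):
        c = codons[i]
        if i > 0 and rng.random() < divergence:
            while True:
                alt = _random_seq(rng, 3)
                if alt not in _STOPS and alt != c:
                    c = alt
                    break
        diverged.append(c)
    diverged.append(_STOPS[rng.integers(0, 3)])
    div_seq = "".join(diverged)

    genome_seq = list(_random_seq(rng, 1200))
    g0, g1 = 100, 700
    genome_seq[g0 : g0 + len(coding)] = coding
    genome_seq[g1 : g1 + len(div_seq)] = div_seq
    seqid = f"pair{seed}"
    genome = GenomeSequence({seqid: "".join(genome_seq)})
    ref_chain = ExonChain.from_pairs(seqid, [(g0, g0 + len(coding))], "+")
    reference = TranscriptRecord(
        transcript_id=f"{seqid}.ref",
        gene_id=f"{seqid}.g",
        exons=ref_chain,
        cds=ref_chain,
    )
    pairs = ([(g0, g0 + 3 * k)] if k else []) + [(g1, g1 + len(div_seq))]
    query_chain = ExonChain.from_pairs(seqid, pairs, "+")
    return genome, reference, query_chain


def make_shared_orf_locus(
    seed: int,
    n_isoforms: int = 4,
    params: SearchParams | None = None,
) -> Locus:
    """A locus whose isoforms all contain the canonical CDS chain intact.

    Isoforms differ only in untranslated structure (jittered outer UTR
    boundaries), so the canonical ORF remains a contiguous
    transcript-space window of every isoform.  Used to probe exact
    recovery of hidden ORFs from partial reference annotation.
    """
    params = params or SearchParams()
    base = make_locus(seed, n_isoforms=1, splice_events=frozenset(), params=params)
    rng = np.random.default_rng((seed + 1) * 7919)
    ref = base.reference
    exons = ref.exons
    cds = ref.cds
    isoforms = []
    for i in range(n_isoforms):
        tx_pairs = [
            (iv.start, iv.end) for iv in exons.intervals
        ]
        if exons.strand == "-":
            tx_pairs = tx_pairs[::-1]
        # jitter the outer UTR boundaries without touching the CDS
        first = list(tx_pairs[0])
        last = list(tx_pairs[-1])
        d5 = int(rng.integers(0, 25))
        d3 = int(rng.integers(0, 25))
        if exons.strand == "+":
            first[0] = max(2, first[0] - d5 if rng.integers(0, 2) else first[0] + d5)
            last[1] = last[1] + d3
            if last[1] > base.genome.length(base.seqid) - 2:
                last[1] = base.genome.length(base.seqid) - 2
            if first[0] >= cds.span_start - 3:
                first[0] = tx_pairs[0][0]
        else:
            first[1] = first[1] + d5
            if first[1] > base.genome.length(base.seqid) - 2:
                first[1] = base.genome.length(base.seqid) - 2
            last[0] = max(2, last[0] - d3)
            if first[1] <= cds.span_end + 3:
                first[1] = tx_pairs[0][1]
        tx_pairs = [tuple(first)] + tx_pairs[1:-1] + [tuple(last)]
        iso_exons = ExonChain.from_pairs(base.seqid, tx_pairs, exons.strand)
        if not iso_exons.contains_chain(cds):
            iso_exons = exons
        rec = TranscriptRecord(
            transcript_id=f"{ref.transcript_id}.iso{i}",
            gene_id=ref.gene_id,
            exons=iso_exons,
            cds=cds,
        )
        isoforms.append(rec)
    return Locus(
        genome=base.genome,
        reference=ref,
        isoforms=isoforms,
        seqid=base.seqid,
        strand=base.strand,
    )
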