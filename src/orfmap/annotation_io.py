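"""Genome FASTA and GTF/GFF3 annotation input/output.

Internal coordinates are always 0-based half-open on the forward strand;
GTF/GFF3 files use 1-based inclusive coordinates and are converted on the
way in and out.  Internal CDS chains *include* the stop codon: on GTF
output the final three coding bases are emitted as ``stop_codon`` features
and excluded from the ``CDS`` lines (GENCODE dialect), while GFF3 output
keeps the stop codon inside the ``CDS`` features (NCBI dialect).  Reading
either dialect therefore produces the same internal chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger("orfmap")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    seqid: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.seqid}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ExonChain:
    """An ordered, merged chain of intervals on one strand.

    Intervals are stored in ascending genomic order; transcript-space
    offsets run 5'->3', i.e. left-to-right on '+' and right-to-left on '-'.
    """

    intervals: tuple[GenomicInterval, ...]
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.intervals:
            raise ValueError("empty exon chain")
        seqid = self.intervals[0].seqid
        prev_end = None
        for iv in self.intervals:
            if iv.seqid != seqid:
                raise ValueError("exon chain spans multiple sequences")
            if prev_end is not None and iv.start <= prev_end:
                raise ValueError("exon chain intervals overlap or touch")
            prev_end = iv.end

    @classmethod
    def from_pairs(
        cls, seqid: str, pairs: Iterable[tuple[int, int]], strand: str
    ) -> "ExonChain":
        """Build a chain from (start, end) pairs, sorting and merging."""
        ivs = sorted((int(s), int(e)) for s, e in pairs)
        if not ivs:
            raise ValueError("no intervals")
        merged: list[list[int]] = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:  # overlap or adjacency -> merge
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return cls(
            tuple(GenomicInterval(seqid, s, e) for s, e in merged), strand
        )

    @property
    def seqid(self) -> str:
        return self.intervals[0].seqid

    @property
    def span_start(self) -> int:
        return self.intervals[0].start

    @property
    def span_end(self) -> int:
        return self.intervals[-1].end

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def _cumulative(self) -> list[int]:
        cum = [0]
        for iv in self.intervals:
            cum.append(cum[-1] + iv.length)
        return cum

    def genomic_to_tx(self, pos: int) -> int | None:
        """Transcript-space offset of a genomic position, or None outside."""
        cum = 0
        for iv in self.intervals:
            if iv.start <= pos < iv.end:
                plus_off = cum + (pos - iv.start)
                if self.strand == "+":
                    return plus_off
                return self.total_length - 1 - plus_off
            cum += iv.length
        return None

    def tx_to_genomic(self, offset: int) -> int:
        """Genomic position of a transcript-space offset."""
        total = self.total_length
        if not 0 <= offset < total:
            raise IndexError(f"offset {offset} outside chain of {total}")
        plus_off = offset if self.strand == "+" else total - 1 - offset
        for iv in self.intervals:
            if plus_off < iv.length:
                return iv.start + plus_off
            plus_off -= iv.length
        raise AssertionError("unreachable")

    def subchain(self, tx_start: int, tx_end: int) -> "ExonChain":
        """Chain covering transcript offsets [tx_start, tx_end)."""
        total = self.total_length
        if not 0 <= tx_start < tx_end <= total:
            raise IndexError(f"window [{tx_start},{tx_end}) outside {total}")
        if self.strand == "+":
            lo, hi = tx_start, tx_end
        else:
            lo, hi = total - tx_end, total - tx_start
        pieces: list[tuple[int, int]] = []
        cum = 0
        for iv in self.intervals:
            a = max(lo, cum)
            b = min(hi, cum + iv.length)
            if a < b:
                pieces.append((iv.start + (a - cum), iv.start + (b - cum)))
            cum += iv.length
        return ExonChain.from_pairs(self.seqid, pieces, self.strand)

    def contains_chain(self, other: "ExonChain") -> bool:
        """True if every base of *other* lies inside this chain."""
        if other.seqid != self.seqid:
            return False
        i = 0
        for o in other.intervals:
            while i < len(self.intervals) and self.intervals[i].end <= o.start:
                i += 1
            if i == len(self.intervals):
                return False
            iv = self.intervals[i]
            if not (iv.start <= o.start and o.end <= iv.end):
                return False
        return True

    def with_strand(self, strand: str) -> "ExonChain":
        return ExonChain(self.intervals, strand)


@dataclass
class TranscriptRecord:
    """One transcript: exon chain plus an optional coding (CDS) chain.

    The CDS chain, when present, includes the stop codon and must be fully
    contained in the exon chain.
    """

    transcript_id: str
    gene_id: str
    exons: ExonChain
    cds: ExonChain | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cds is not None:
            if self.cds.strand != self.exons.strand:
                raise ValueError(
                    f"{self.transcript_id}: CDS strand differs from exons"
                )
            if not self.exons.contains_chain(self.cds):
                raise ValueError(
                    f"{self.transcript_id}: CDS escapes exon chain"
                )

    @property
    def seqid(self) -> str:
        return self.exons.seqid

    @property
    def strand(self) -> str:
        return self.exons.strand

    def copy(self) -> "TranscriptRecord":
        return replace(self, attributes=dict(self.attributes))


class GenomeSequence:
    """Uppercased nucleotide sequences keyed by seqid."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def __contains__(self, seqid: str) -> bool:
        return seqid in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def length(self, seqid: str) -> int:
        return len(self._seqs[seqid])

    def fetch(self, seqid: str, start: int, end: int) -> str:
        seq = self._seqs[seqid]
        if not 0 <= start <= end <= len(seq):
            raise IndexError(
                f"slice {seqid}:{start}-{end} outside [0,{len(seq)})"
            )
        return seq[start:end]

    def sequence(self, seqid: str) -> str:
        return self._seqs[seqid]


def spliced_sequence(chain: ExonChain, genome: GenomeSequence) -> str:
    """Spliced 5'->3' nucleotide sequence of a chain."""
    if chain.seqid not in genome:
        raise KeyError(f"sequence {chain.seqid!r} not in genome")
    parts = [genome.fetch(chain.seqid, iv.start, iv.end) for iv in chain.intervals]
    seq = "".join(parts)
    return seq if chain.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> GenomeSequence:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AnnotationError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise AnnotationError(f"no sequences found in {path}")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seqid in genome:
            fh.write(f">{seqid}\n")
            seq = genome.sequence(seqid)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF3 reading
# ---------------------------------------------------------------------------

_TX_TYPES = {"transcript", "mRNA"}
_PART_TYPES = {"exon", "CDS", "stop_codon"}


def _sniff_format(path: str | Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                continue
            attrs = fields[8]
            if "=" in attrs.split(";")[0] and '"' not in attrs.split(";")[0]:
                return "gff3"
            return "gtf"
    raise AnnotationError(f"{path}: no feature lines found")


def _transcript_id_of(feature, fmt: str, lineno: int):
    attrs = feature.attributes
    if fmt == "gtf":
        vals = attrs.get("transcript_id")
        return vals[0] if vals else None
    if feature.featuretype in _TX_TYPES:
        vals = attrs.get("ID")
        return vals[0] if vals else None
    vals = attrs.get("Parent")
    if vals and len(vals) > 1:
        raise AnnotationError(
            f"line {lineno}: multi-parent features are not supported"
        )
    return vals[0] if vals else None


def read_annotation(
    path: str | Path, format: str = "auto"
) -> list[TranscriptRecord]:
    """Read a GTF or GFF3 file into transcript records.

    Exon, CDS and stop_codon features are grouped under their transcript;
    stop_codon features are merged into the internal CDS chain.  Records
    missing exon features but carrying CDS features get exons synthesized
    from the CDS chain.  Output is sorted by (seqid, first exon start).
    """
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("gtf", "gff3"):
        raise ValueError(f"unknown format {fmt!r}")

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    def bucket(tid: str) -> dict:
        if tid not in meta:
            meta[tid] = {
                "seqid": None,
                "strand": None,
                "gene_id": None,
                "attributes": {},
            }
            order.append(tid)
        return meta[tid]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationError(
                    f"{path} line {lineno}: expected 9 tab-separated columns"
                )
            try:
                feature = feature_from_line(line.rstrip("\n"))
            except Exception as exc:  # gffutils raises bare exceptions
                raise AnnotationError(
                    f"{path} line {lineno}: cannot parse: {exc}"
                ) from exc
            ftype = feature.featuretype
            if ftype not in _PART_TYPES and ftype not in _TX_TYPES:
                continue
            tid = _transcript_id_of(feature, fmt, lineno)
            if tid is None:
                if ftype in _TX_TYPES:
                    continue  # e.g. a gene-level record without ID
                raise AnnotationError(
                    f"{path} line {lineno}: {ftype} feature with no "
                    "transcript/Parent id"
                )
            info = bucket(tid)
            if info["seqid"] is None:
                info["seqid"] = feature.seqid
            elif info["seqid"] != feature.seqid:
                raise AnnotationError(
                    f"{path} line {lineno}: transcript {tid} spans sequences"
                )
            if feature.strand not in ("+", "-"):
                raise AnnotationError(
                    f"{path} line {lineno}: missing/invalid strand"
                )
            if info["strand"] is None:
                info["strand"] = feature.strand
            elif info["strand"] != feature.strand:
                raise AnnotationError(
                    f"{path} line {lineno}: transcript {tid} on mixed strands"
                )
            gid = feature.attributes.get("gene_id") or (
                feature.attributes.get("geneID") if fmt == "gff3" else None
            )
            if gid and info["gene_id"] is None:
                info["gene_id"] = gid[0]
            iv = (feature.start - 1, feature.end)  # to 0-based half-open
            if iv[0] >= iv[1]:
                raise AnnotationError(
                    f"{path} line {lineno}: empty feature interval"
                )
            if ftype == "exon":
                exons.setdefault(tid, []).append(iv)
            elif ftype in ("CDS", "stop_codon"):
                cds.setdefault(tid, []).append(iv)
            else:  # transcript-level feature: harvest attributes
                skip = {"transcript_id", "gene_id", "ID", "Parent"}
                for key, vals in feature.attributes.items():
                    if key not in skip:
                        info["attributes"][key] = vals[0]

    records: list[TranscriptRecord] = []
    for tid in order:
        info = meta[tid]
        if tid not in exons and tid not in cds:
            continue  # transcript line with no parts
        cds_chain = None
        if tid in cds:
            cds_chain = ExonChain.from_pairs(
                info["seqid"], cds[tid], info["strand"]
            )
        if tid in exons:
            exon_chain = ExonChain.from_pairs(
                info["seqid"], exons[tid], info["strand"]
            )
        else:
            exon_chain = cds_chain  # synthesize exons from CDS
        try:
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_id=info["gene_id"] or tid,
                    exons=exon_chain,
                    cds=cds_chain,
                    attributes=info["attributes"],
                )
            )
        except ValueError as exc:
            raise AnnotationError(f"{path}: {exc}") from exc
    records.sort(key=lambda r: (r.seqid, r.exons.span_start, r.transcript_id))
    return records


# ---------------------------------------------------------------------------
# GTF / GFF3 writing
# ---------------------------------------------------------------------------

def cds_phases(cds: ExonChain) -> list[int]:
    """GTF/GFF frame column per CDS interval, accumulated 5'->3'.

    The phase is the number of bases to skip at the start of the piece to
    reach the next codon boundary: (3 - coding_bases_before % 3) % 3.
    """
    ivs = list(cds.intervals)
    if cds.strand == "-":
        ivs = ivs[::-1]
    phases = []
    before = 0
    for iv in ivs:
        phases.append((3 - before % 3) % 3)
        before += iv.length
    if cds.strand == "-":
        phases = phases[::-1]
    return phases


def _fmt_attrs_gtf(record: TranscriptRecord) -> str:
    parts = [
        f'transcript_id "{record.transcript_id}"',
        f'gene_id "{record.gene_id}"',
    ]
    parts += [f'{k} "{v}"' for k, v in record.attributes.items()]
    return "; ".join(parts) + ";"


def _fmt_attrs_gff3(record: TranscriptRecord, part: str | None) -> str:
    if part is None:
        parts = [f"ID={record.transcript_id}", f"gene_id={record.gene_id}"]
        parts += [f"{k}={v}" for k, v in record.attributes.items()]
    else:
        parts = [f"Parent={record.transcript_id}"]
    return ";".join(parts)


def format_annotation(
    records: Sequence[TranscriptRecord],
    format: str = "gtf",
    source: str = "orfmap",
) -> str:
    """Render records as GTF or GFF3 text, sorted by (seqid, start)."""
    if format not in ("gtf", "gff3"):
        raise ValueError(f"unknown format {format!r}")
    recs = sorted(
        records, key=lambda r: (r.seqid, r.exons.span_start, r.transcript_id)
    )
    lines: list[str] = []
    if format == "gff3":
        lines.append("##gff-version 3")

    def emit(rec, ftype, iv, frame=".", part=True):
        attrs = (
            _fmt_attrs_gtf(rec)
            if format == "gtf"
            else _fmt_attrs_gff3(rec, ftype if part else None)
        )
        lines.append(
            "\t".join(
                [
                    rec.seqid,
                    source,
                    ftype,
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    rec.strand,
                    str(frame),
                    attrs,
                ]
            )
        )

    for rec in recs:
        span = GenomicInterval(
            rec.seqid, rec.exons.span_start, rec.exons.span_end
        )
        emit(rec, "transcript" if format == "gtf" else "mRNA", span, part=False)
        for iv in rec.exons.intervals:
            emit(rec, "exon", iv)
        if rec.cds is not None:
            total = rec.cds.total_length
            if format == "gtf" and total > 3:
                coding = rec.cds.subchain(0, total - 3)
                stop = rec.cds.subchain(total - 3, total)
                for iv, ph in zip(coding.intervals, cds_phases(coding)):
                    emit(rec, "CDS", iv, frame=ph)
                stop_ivs = list(stop.intervals)
                stop_phases = cds_phases(stop)
                for iv, ph in zip(stop_ivs, stop_phases):
                    emit(rec, "stop_codon", iv, frame=ph)
            else:
                for iv, ph in zip(rec.cds.intervals, cds_phases(rec.cds)):
                    emit(rec, "CDS", iv, frame=ph)
    return "\n".join(lines) + "\n"


def write_annotation(
    records: Sequence[TranscriptRecord],
    path: str | Path,
    format: str = "gtf",
    source: str = "orfmap",
) -> None:
    """Write records as GTF or GFF3 (see :func:`format_annotation`)."""
    with open(path, "w") as fh:
        fh.write(format_annotation(records, format, source))
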