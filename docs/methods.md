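# Methods

## Model and assumptions

`orfmap` assigns ORFs to query transcripts by maximizing similarity to a
set of reference ORFs through direct comparison of genomic exon chains.
The underlying assumptions are those of reference-guided annotation:
alternative isoforms of a gene should encode proteins similar to the
curated one, similarity can be measured on shared genomic codons without
alignment, and a transcript that cannot host an ORF resembling any
reference at its locus is best left non-coding. The method does not
model selenoprotein UGA readthrough, non-ATG initiation (unless the
start-codon set is extended), polycistronic transcripts, or de novo ORF
discovery away from reference overlap.

All coordinates are internally 0-based half-open on the forward strand;
transcript-space offsets run 5'→3'. Internal CDS chains include the stop
codon; GTF output emits the stop as `stop_codon` features excluded from
`CDS` lines (GENCODE dialect) while GFF3 output keeps it inside the CDS
(NCBI dialect), so reading either dialect reconstructs the same chain.

## Scores and selection

For a candidate ORF and one reference CDS:

- **IL** counts bases of *complete* shared codons: a candidate codon
  contributes 3 iff its three genomic bases are consecutive coding bases
  of the reference with the same codon boundary. Counting whole codons
  (rather than raw shared bases) keeps IL a multiple of 3 even when
  interval sharing ends mid-codon at a splice junction, and matches the
  intended meaning — positions coding for the same codon.
- **ILPI** = IL / reference coding length. Stop codons are excluded from
  IL, from the reference length, and from candidate length: they encode
  no residue.
- **novel bases**: candidate coding bases not covered by the reference
  CDS in any frame.

Selection is two-level.

1. *Within one stop* (one reading frame ending at a fixed stop codon),
   the start is chosen per reference: among in-frame start codons with no
   intervening stop or ambiguous codon, take the one maximizing IL
   against that reference, breaking ties toward the fewest non-matching
   bases (the 3'-most, least-novel start). Only these per-reference
   optimal starts become candidates.
2. *Across candidates*, a mode-dependent cascade ranks the per-candidate
   best score over all references in the bundle: `ilpi` mode uses
   (ILPI, fewest novel bases, IL, length); `il` mode uses (IL, ILPI,
   fewest novel bases, length); final ties go to the 5'-most
   transcript-space start, making output deterministic.

Placing novel-base minimization directly behind ILPI is deliberate: with
several overlapping references, a candidate extended by an extra
upstream codon can reproduce a sibling isoform's ORF completely and
would, under a bare (ILPI, IL, length) cascade, displace the exact
reproduction of the transcript's own reference purely by length. The
chosen order guarantees that an ORF reproducing a reference exactly with
zero unsupported sequence is never displaced by a padded one, which in
turn makes self-annotation the identity and hidden-ORF recovery exact
for contained ORFs. In `il` mode match count deliberately outranks
everything, so longer ORFs with novel sequence win when they add
matched bases.

Candidates whose IL is zero against every reference are discarded: the
search is reference-guided, and emitting an unrelated ORF merely because
it is long would be de novo prediction, which is out of scope.

## Validity rules

A valid ORF starts with a codon from the start set (default `{ATG}`),
ends with the first in-frame stop (default `{TAA, TAG, TGA}`), contains
no internal stop, and spans at least `min_orf_length` coding codons
(default 1). Codons containing N match neither set and break the frame:
a candidate interrupted by an ambiguous codon is discarded. References
failing these rules are dropped with a warning before the search;
`clean_reference` additionally removes both members of any pair of
overlapping CDS chains with different gene ids, mirroring standard
pre-evaluation filtering of curation exceptions.

## Bundling

References are grouped per (seqid, strand) — and per gene id when
requested — by a left-to-right sweep over CDS genomic spans; overlapping
spans merge into one bundle. Queries attach to every bundle containing a
reference whose CDS span overlaps the query exon span on the same
strand; a readthrough query joining several bundles is searched in each
and the global cascade picks one winner. Bundles are independent, so the
thread count cannot affect results; correctness is checked against
brute-force connected components rather than by operation counting.

## Synthetic data

The fixture generator emulates an assembly-like evaluation substrate: a
3–10 kb random-uniform genome containing one multi-exon gene (3–6 exons,
3–30 codons each) with an embedded ORF guaranteed valid, random UTRs and
introns, and isoforms derived by one splicing event each — exon
skipping, alternative first exon, alternative 3' splice site, or intron
retention. Splice points fall at arbitrary codon phases. Ground-truth
ORFs for isoforms come from the brute-force oracle, which enumerates
every valid (start, stop) pair in the spliced sequence by direct codon
scanning and applies the selection definition above; it shares the
scoring routine and data types with the package but none of the
interval-walking search machinery.

What the generator does not model: splice-site motifs, codon usage and
GC bias, expression levels, sequencing noise, genuinely overlapping
genes, and curation idiosyncrasies. Passing tests therefore demonstrate
algorithmic correctness of the search, scoring and selection on
realistic exon-intron geometries — not robustness to annotation errors
in real references.

Two special-purpose generators support evaluation designs: loci whose
isoforms differ only in UTR structure (the canonical CDS is contained in
every isoform), used to probe exact recovery of hidden ORFs; and
query/reference ORF pairs sharing a controlled fraction of codons
genomically while the remainder is a diverged copy (0.5 mutation
probability per codon), used for the ILPI-versus-percent-identity
concordance experiment. The divergence keeps the local alignment
spanning the whole protein, as it does for real homologous isoforms;
with fully random remainders, local-alignment identity saturates on the
shared block and the comparison degenerates.

## Numerical and interface choices

- Protein identity uses Smith-Waterman local alignment with BLOSUM62,
  affine gaps (open 10, extend 1) — the EMBOSS default family — and
  reports matches over aligned columns, gap columns included.
- "Matches canonical" in the comparison module means exact genomic
  CDS-chain equality; chain equality implies protein equality but not
  conversely, so category counts are conservative.
- Canonical ORFs are matched to transcripts by largest CDS-span overlap
  on the same strand, not by gene symbol.
- Frame/phase columns on output follow the GTF/GFF convention (bases to
  skip to the next codon boundary), accumulated 5'→3' per CDS chain.
- All randomness is seed-derived (`numpy.random.default_rng`); identical
  seeds give byte-identical FASTA/GTF fixtures, and the annotation path
  contains no randomness at all.

## Problem sizes

The shipped test suite and acceptance script run on generated loci at
these scales, chosen to exercise every code path many hundreds of times
while keeping a full run in the tens of seconds: 500 loci × 3 isoforms ×
2 modes for oracle equivalence; 150 loci for self-annotation; 200 loci ×
3 hidden isoforms for exact recovery plus 100 loci × 3 nested guide
fractions for the monotonicity check; 220 pairs spanning ILPI 0–1 for
the concordance experiment; 100 random interval sets for bundling; 50
mirrored loci for strand symmetry.

## Known limitations

- Query attachment in bundling scans bundles per (seqid, strand) rather
  than using an interval index; linear-time behavior is practical, not
  instrumented.
- A query bridging two genes (readthrough) is scored in both bundles and
  receives the single globally best ORF; no readthrough detection or
  splitting is attempted.
- With several references of different lengths at one locus, `il` mode
  can legitimately prefer an ORF matching a longer sibling isoform over
  an exact short match; this is the documented intent of that mode, not
  an error.
- Multi-parent GFF3 features, BAM input, FASTA indexes and circular
  chromosomes are unsupported.
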