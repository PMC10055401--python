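# orfmap

Reference-guided open reading frame (ORF) assignment for transcript
annotations, built on exon-chain interval comparison instead of sequence
alignment.

Transcriptome assemblies (e.g. StringTie output from bulk or single-cell
RNA-seq) describe novel isoforms as chains of exons with no coding
information. `orfmap` takes a genome (FASTA), a reference annotation with
CDS features (GTF/GFF3), and query transcripts (GTF/GFF3), and assigns to
each query the ORF that best reproduces the protein of a reference ORF at
the same locus. It is aimed at annotation curators and RNA-seq analysts
who need CDS features on assembled transcripts that stay maximally
consistent with a curated reference.

## Method

For a query transcript *q* and a reference CDS *r* on the same strand,
the intersection of their exon chains identifies the genomic intervals
shared by both. Each shared interval implies a reading frame on *q* (the
frame *r* uses at those bases). Candidate ORFs are grown from these
anchors: downstream to the single reachable stop codon, upstream to the
start codon that maximizes the number of reference codons reproduced in
frame while minimizing unmatched sequence. Every candidate is scored
against every reference in its locus bundle with three quantities:

- **IL** (in-frame length): number of coding bases whose whole codon is
  shared with the reference in the same reading frame, so query and
  reference encode the same codon there;
- **ILPI** = IL / reference coding length (stop codons excluded
  everywhere): the fraction of reference codons the candidate reproduces,
  an alignment-free stand-in for protein percent identity;
- **length**: the candidate's coding length.

In the default `ilpi` mode candidates are ranked by ILPI, then fewest
novel bases (coding bases the reference does not cover), then IL, then
length; in `il` mode by IL, then ILPI, then fewest novel bases, then
length. Remaining ties go to the 5'-most start. A selected ORF is always
a valid reading frame — start codon, stop codon, no internal stop, length
divisible by 3 — verified on the spliced sequence.

Loci are processed as independent *bundles* (connected components of
reference CDS spans plus the queries overlapping them), so runs
parallelize per bundle and output is identical at any thread count.

## Worked example

Generate a synthetic three-isoform locus and annotate it against its own
reference:

```
$ orfmap fixtures --seed 11 --isoforms 3 --out-prefix l11
$ orfmap annotate --reference l11.reference.gtf --query l11.query.gtf \
      --genome l11.fa --output annotated.gtf --stats stats.tsv --align
$ cat stats.tsv
transcript_id     reference_id  il   ilpi    length  sw_identity
locus11.ref.iso1  locus11.ref   96   0.6809  162     0.9429
locus11.ref.iso0  locus11.ref   42   0.2979  228     1.0000
locus11.ref.iso2  locus11.ref   42   0.2979  228     1.0000
```

Isoform 1 reproduces 96 of the reference's 141 coding bases in frame
(ILPI 0.68) and its protein aligns at 94% identity to the reference
protein. Isoforms 0 and 2 lost the reference start through a splicing
event; the selected downstream ORF keeps 42 in-frame bases (14 reference
codons) and extends with novel sequence, while its local protein
alignment against the reference is a perfect 42-base core (identity
1.00 over the aligned region — exactly the situation where ILPI is the
more informative, length-normalized measure). `annotated.gtf` carries the
selected CDS and stop_codon features with correct frame/phase columns.

`orfmap compare` classifies an annotated set against the original and a
canonical annotation (same ORF / replaced by canonical / newly found /
other) and writes per-transcript and summary TSVs.

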