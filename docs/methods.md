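# Methods

## Coordinate and strand conventions

All genomic coordinates are 0-based half-open (`[start, end)`), the
UCSC table convention. RepeatMasker `.out` files (1-based inclusive)
are converted on read, so the same hit read through either dialect is
bit-identical. Repeat-consensus coordinates are stored 0-based
half-open in consensus-forward orientation for both genomic strands,
giving the consensus splice-site profile a single frame of reference.
Strand `.` (unstranded) is legal for TEs; such elements are excluded
from orientation tallies but counted in every other statistic.

## TE context classification

"Found within" means ≥ 1 bp of overlap throughout. Labels form a
partition assigned by precedence:

1. **exonized** — the TE overlaps an *internal* block of some alignment
   and the block's first or last exonic base lies inside the TE span.
   The boundary base is the least arbitrary reading of "the splice site
   lies within the TE"; no window parameter is introduced. When a
   genome is supplied the flanking intron dinucleotides must also be
   canonical.
2. **exonic_terminal** — block overlap confined to first/last blocks of
   every supporting alignment. Terminal blocks are never treated as
   spliced exons: their outer edge is an alignment end, not a splice
   site, which is why they are also excluded from exonization calls.
3. **exonic_internal_nonspliced** — internal-block overlap without a
   splice site in the TE (e.g. a TE wholly inside a coding exon).
4. **intronic** — overlap only with alignment gaps.
5. **intergenic** — no overlap with any alignment.

Under these rules the precedence is total, so the reserved `ambiguous`
label is never emitted; it remains in the schema (and as its own report
row) for data where conflicting evidence cannot be ordered.
`in_refseq_gene` is ≥ 1 bp overlap with any gene-model transcript span
and drives the RefSeq / non-RefSeq split of the summary table.

Classification is monotone: adding alignments can only move a TE away
from *intergenic*, never toward it (verified as a property test).

## Exonization detection and splicing patterns

An event requires (i) TE overlap of an internal block, (ii) canonical
splice sites — GT donor and AG acceptor read on the transcript strand;
GC–AG donors are accepted only behind an off-by-default flag — and
(iii) a splice-boundary base inside a TE. Events are deduplicated on
exact `(chrom, start, end, strand)`; near-duplicates a few bp apart are
kept, because collapsing them would hide genuine alternative-splice-
site usage. The event list is independent of input order (alignments
are processed in transcript-id order, TE hits in coordinate order).

Pattern classification uses *spanning* alignments — those with blocks
strictly upstream and strictly downstream of the event exon:

* **cassette**: some spanning alignment has one intron covering the
  whole exon (flank-to-flank splicing);
* **alt5 / alt3**: another alignment's exon shares the acceptor (donor)
  boundary and shifts the donor (acceptor), strand-aware;
* **constitutive**: ≥ 2 spanning alignments, all including the exon
  with identical boundaries. The two-alignment minimum guards against
  sparse EST coverage inflating constitutive calls;
* **unclassified** otherwise.

Priority under conflicting evidence is cassette > alt5/alt3 >
constitutive; when both alternative-site kinds occur the rarer one
(fewest supporting alignments) is reported, ties to alt5.

## Frame analysis

Placement is CDS when the event exon overlaps `[cds_start, cds_end)` of
a same-strand gene, UTR when it overlaps the gene otherwise. For CDS
events the reading frame is inherited from the coding exons
transcript-upstream of the insertion point; codons lying fully inside
the new exon are scanned for TAA/TAG/TGA. The same frame rule accepts
internal-coding-exon TE insertions when the TE length is a multiple of
three and no codon fully inside the TE span is a stop — insertions that
extend a protein rather than disrupt it; flanking intron lengths are
reported with each.

## Intron and terminal-exon metrics

Intron metrics use gene-model introns with one isoform per gene (the
first annotated), a distinct data path from the EST gaps used in
classification. TE bp is the union length (overlapping copies counted
once), so `length − TE bp ≥ 0` holds per intron; medians are
midpoint-of-sorted. Terminal-exon statistics select one transcript per
gene by longest CDS (ties to input order), identify first/last exons in
transcript orientation, skip single-exon genes by default, and report
100 × (summed union TE bp) / (summed exon bp). The UTR enrichment test
compares observed UTR:CDS event counts against the gene models' own
exonic UTR:CDS bp ratio by χ² goodness of fit.

## Statistical procedures

Pearson χ² (contingency and goodness of fit) is computed from the
closed form without continuity correction — the analyses it supports
are large-count, and applying Yates would not reproduce uncorrected
extreme p-values. The 2×2 Fisher exact test enumerates the
hypergeometric support with exact integer weights and sums the
probabilities of tables no more probable than the observed one, so tie
handling is exact rather than tolerance-based; scipy's implementation
serves as an independent cross-check in the tests, never as the
implementation. The KS normality screen standardises by sample moments
(conservative with estimated parameters); the t-test is Welch by
default, as equal variances are rarely defensible for intron-length
comparisons.

## Synthetic genomes

The generator emulates the structure the analysis assumes, on one
chromosome per run: non-overlapping multi-exon genes (4–8 exons of
80–220 bp by default) separated by ≥ 1.5 kb intergenic spacers, with
lognormal intron lengths. Presets cover the architectures that matter
for exonization: "fly-like" (median 72 bp), "worm-like" (median
700 bp, the default) and "vertebrate-like" (median 3 kb). TE insertions
are Poisson-placed per intron/spacer at per-family per-kb densities
(defaults 0.8/0.5/0.3/0.5 for SINE/LINE/LTR/DNA), with per-family
antisense probabilities defaulting to 0.5 except LINE 0.6 and LTR 0.7
(retroelements fix preferentially antisense to the host transcript).
SINE consensus length is 402 bp, mirroring the tRNA-derived HE1 family.

Exonizations are planted inside intronic TEs (at most one per intron)
by writing canonical dinucleotides into the sequence at the chosen exon
boundaries; the pattern mix defaults to 0.5/0.2/0.2/0.1 over
cassette/alt5/alt3/constitutive. EST sampling guarantees the planted
pattern is observable: the first two ESTs of each gene are untruncated,
with the first including the primary isoform and the second skipping
(cassette), carrying the alternative boundary (alt5/alt3) or including
(constitutive); further ESTs choose forms at random and may be
truncated at a uniform random 5' position (probability 0.2), which
exercises the first/last-block exclusion logic. In-frame stop content
of coding planted exons and of internal-CDS TE insertions is controlled
codon-by-codon (stop-free rewrites, or one planted TAA for
disqualified/stop-carrying cases); these frame plants are placed in
plus-strand host genes to keep the generator's bookkeeping simple,
while the detector itself is strand-general and minus-strand frame
logic is unit-tested on hand-built models.

Background sequence is i.i.d. uniform ACGT with no codon or composition
model: the pipeline reads sequence only at splice-site dinucleotides
and stop codons, both planted explicitly. The generator therefore does
*not* emulate splice-site strength, polypyrimidine tracts, TE sequence
divergence, alignment error or EST chimerism — passing tests show the
pipeline's logic is correct on its own terms, not that real noisy
alignments would be handled gracefully. Everything is deterministic
given the seed (same seed, byte-identical files).

## Problem sizes and numerical choices

Oracle-equivalence testing runs ten seeded genomes of roughly 1 Mb
(~100 genes, ~2,000 TEs, EST depth 5), where interval-tree
classification is compared per TE with an exhaustive per-base oracle;
recovery testing uses EST depth 10 with ~30% of eligible intronic TEs
exonized. Fisher enumeration agreement is checked exhaustively for all
2×2 tables with n ≤ 60 at 1e-12 and the χ² closed form on 1,000 random
tables at 1e-9. These sizes keep the full suite around half a minute
while exercising every code path at realistic densities.

Degenerate inputs raise typed errors rather than returning sentinels:
empty intron sets, zero-variance correlations, zero-margin contingency
tables, percentages with zero denominators and infeasible generator
configurations (e.g. every region shorter than the minimum TE length)
are all rejected with messages naming the constraint.

## Known limitations

EST strands are taken from the alignment records as-is; no correction
of transcript orientation from splice-site dinucleotides is attempted,
so orientation tallies inherit any strand errors in the input. GFF3/GTF
ingestion, compressed/indexed access, splice-site strength scoring and
any evolutionary modelling (insertion age, selection) are out of scope.
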