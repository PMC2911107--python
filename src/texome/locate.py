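"""Per-TE genomic-context classification from spliced-alignment evidence.

Every TE receives exactly one label, assigned by precedence::

    exonized > exonic_terminal > exonic_internal_nonspliced > intronic > intergenic

* ``exonized`` — the TE overlaps an internal exon block of some alignment
  and at least one of that block's splice-boundary bases lies inside the
  TE's genomic span (optionally the flanking intron dinucleotides must be
  canonical GT–AG when a genome is supplied);
* ``exonic_terminal`` — the TE overlaps alignment blocks, but only first
  or last blocks of the supporting alignments (mirrors the exclusion of
  EST/cDNA terminal exons from exonization calls);
* ``exonic_internal_nonspliced`` — the TE overlaps an internal block but
  contributes no splice site;
* ``intronic`` — the TE overlaps only gaps (introns) of the supporting
  alignments;
* ``intergenic`` — no overlap with any alignment at all.

"Found within" means >= 1 bp of overlap throughout.  The ``ambiguous``
label is reserved in the schema for conflicting evidence that the
precedence above cannot order; under these rules the precedence is total,
so it is never emitted (it remains a legal label and its own report row).

``in_refseq_gene`` is true iff the TE overlaps any gene-model transcript
span; this drives the intronic-within-RefSeq vs non-RefSeq split of the
summary tables.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import (
    GeneModel,
    SplicedAlignment,
    TEAnnotation,
    TEContext,
    TE_FAMILIES,
    revcomp,
)


class AlignmentIndex:
    """Interval indexes over alignment blocks and gaps, per chromosome."""

    def __init__(self, alignments: Sequence[SplicedAlignment]):
        self.alignments = list(alignments)
        self.block_trees: dict[str, IntervalTree] = {}
        self.gap_trees: dict[str, IntervalTree] = {}
        self.strand_of: dict[str, str] = {}
        for ai, aln in enumerate(self.alignments):
            self.strand_of[aln.tx_id] = aln.strand
            bt = self.block_trees.setdefault(aln.chrom, IntervalTree())
            n = len(aln.blocks)
            for bi, b in enumerate(aln.blocks):
                bt.addi(b.start, b.end, (ai, bi, n))
            gt = self.gap_trees.setdefault(aln.chrom, IntervalTree())
            for g in aln.introns():
                gt.addi(g.start, g.end, ai)

    def blocks_overlapping(self, chrom: str, start: int, end: int):
        tree = self.block_trees.get(chrom)
        return tree.overlap(start, end) if tree is not None else ()

    def gaps_overlapping(self, chrom: str, start: int, end: int):
        tree = self.gap_trees.get(chrom)
        return tree.overlap(start, end) if tree is not None else ()


class GeneIndex:
    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self.trees: dict[str, IntervalTree] = {}
        for gi, g in enumerate(self.genes):
            self.trees.setdefault(g.chrom, IntervalTree()).addi(
                g.tx_start, g.tx_end, gi
            )

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[hit.data] for hit in sorted(tree.overlap(start, end))]


def _block_splices_in_te(
    te: TEAnnotation,
    aln: SplicedAlignment,
    bi: int,
    genome: Optional[dict[str, str]],
) -> bool:
    """True if internal block *bi* of *aln* has a splice-boundary base
    inside the TE (and canonical GT–AG flanks when *genome* is given)."""
    b = aln.blocks[bi]
    s, e = te.interval.start, te.interval.end
    if not (s <= b.start < e or s <= b.end - 1 < e):
        return False
    if genome is None:
        return True
    seq = genome[aln.chrom]
    left, right = seq[b.start - 2 : b.start], seq[b.end : b.end + 2]
    if aln.strand == "+":
        return left == "AG" and right == "GT"
    return revcomp(right) == "AG" and revcomp(left) == "GT"


def classify_tes(
    tes: Sequence[TEAnnotation],
    alignments: Sequence[SplicedAlignment],
    genes: Sequence[GeneModel],
    genome: Optional[dict[str, str]] = None,
) -> list[TEContext]:
    """Classify every TE; the result is a partition (one label per TE)."""
    aidx = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    gidx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify_te(te, aidx, gidx, genome) for te in tes]


def classify_te(
    te: TEAnnotation,
    alignments,
    genes,
    genome: Optional[dict[str, str]] = None,
) -> TEContext:
    """Assign one TE its genomic context (see module docstring)."""
    aidx = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    gidx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    iv = te.interval

    exonized_tx: set[str] = set()
    block_tx: set[str] = set()
    internal_overlap = False
    for hit in aidx.blocks_overlapping(iv.chrom, iv.start, iv.end):
        ai, bi, n = hit.data
        aln = aidx.alignments[ai]
        block_tx.add(aln.tx_id)
        if 0 < bi < n - 1:
            internal_overlap = True
            if _block_splices_in_te(te, aln, bi, genome):
                exonized_tx.add(aln.tx_id)

    gap_tx = {
        aidx.alignments[hit.data].tx_id
        for hit in aidx.gaps_overlapping(iv.chrom, iv.start, iv.end)
    }

    if exonized_tx:
        label, evidence = "exonized", exonized_tx
    elif block_tx:
        label = "exonic_internal_nonspliced" if internal_overlap else "exonic_terminal"
        evidence = block_tx
    elif gap_tx:
        label, evidence = "intronic", gap_tx
    else:
        label, evidence = "intergenic", set()

    in_refseq = bool(gidx.overlapping(iv.chrom, iv.start, iv.end))
    return TEContext(
        te_id=te.te_id,
        label=label,
        in_refseq_gene=in_refseq,
        evidence_tx=sorted(evidence),
    )


def orientation(te: TEAnnotation, tx_strand: str) -> str:
    """'sense' iff the TE strand equals the transcript strand.

    Raises ``ValueError`` for unstranded TEs (undefined orientation; such
    TEs are excluded from orientation counts, never dropped elsewhere).
    """
    if te.interval.strand not in ("+", "-"):
        raise ValueError(f"{te.te_id}: orientation undefined for unstranded TE")
    if tx_strand not in ("+", "-"):
        raise ValueError(f"orientation undefined for transcript strand {tx_strand!r}")
    return "sense" if te.interval.strand == tx_strand else "antisense"


def orientation_bias_table(
    contexts: Sequence[TEContext],
    tes: Sequence[TEAnnotation],
    alignments: Sequence[SplicedAlignment],
) -> pd.DataFrame:
    """Per-family sense/antisense counts over intronic TEs.

    Transcript strand is taken from the supporting alignments as-is
    (majority vote; ties and unstranded TEs are excluded).  Test the
    counts against a 50:50 expectation with
    :func:`texome.stats.chi2_goodness_of_fit`.
    """
    aidx = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    by_id = {te.te_id: te for te in tes}
    table = pd.DataFrame(0, index=list(TE_FAMILIES), columns=["sense", "antisense"])
    for ctx in contexts:
        if ctx.label != "intronic":
            continue
        te = by_id[ctx.te_id]
        if te.interval.strand not in ("+", "-"):
            continue
        strands = [aidx.strand_of[tx] for tx in ctx.evidence_tx if tx in aidx.strand_of]
        plus = sum(1 for s in strands if s == "+")
        minus = sum(1 for s in strands if s == "-")
        if plus == minus:
            continue
        tx_strand = "+" if plus > minus else "-"
        table.loc[te.rep_family, orientation(te, tx_strand)] += 1
    return table
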