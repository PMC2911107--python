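"""First/last-exon lengths and their TE base-pair content.

TE insertions into terminal exons elongate them and mostly land in the
UTR; the quantities here are the average first/last exon length over
genes and the percentage of terminal-exon base pairs of TE origin.
Per gene one transcript is used: the one with the longest CDS (ties
resolved by input order).  Single-exon genes are skipped by default
(their one exon is both first and last; pass ``single_exon="both"`` to
count it on both sides).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    GeneModel,
    StatResult,
    TEAnnotation,
    UndefinedStatisticError,
    overlap_bp,
    union_overlap_bp,
)
from .exonize import locate_in_gene
from .locate import GeneIndex
from .stats import chi2_goodness_of_fit


def longest_cds_isoforms(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """One transcript per gene: longest CDS, ties to first input order."""
    best: dict[str, GeneModel] = {}
    order: list[str] = []
    for g in genes:
        if g.gene_id not in best:
            best[g.gene_id] = g
            order.append(g.gene_id)
        elif g.cds_len() > best[g.gene_id].cds_len():
            best[g.gene_id] = g
    return [best[k] for k in order]


def terminal_exon_stats(
    genes: Sequence[GeneModel],
    tes: Sequence[TEAnnotation],
    single_exon: str = "skip",
) -> dict[str, float]:
    """Average first/last exon lengths and % TE bp within them.

    ``pct_te_bp_*`` is 100 x (union TE bp in the terminal exon, summed
    over genes) / (total terminal-exon bp).
    """
    if single_exon not in ("skip", "both"):
        raise ValueError("single_exon must be 'skip' or 'both'")
    tree: dict[str, IntervalTree] = {}
    for ti, te in enumerate(tes):
        tree.setdefault(te.interval.chrom, IntervalTree()).addi(
            te.interval.start, te.interval.end, ti
        )

    def _te_bp(exon):
        t = tree.get(exon.chrom)
        if t is None:
            return 0
        ivs = [tes[h.data].interval for h in t.overlap(exon.start, exon.end)]
        return union_overlap_bp(exon, ivs)

    first_lens, last_lens = [], []
    first_te = last_te = 0
    for gene in longest_cds_isoforms(genes):
        if len(gene.exons) == 1 and single_exon == "skip":
            continue
        fe, le = gene.first_exon(), gene.last_exon()
        first_lens.append(fe.length())
        last_lens.append(le.length())
        first_te += _te_bp(fe)
        last_te += _te_bp(le)
    if not first_lens:
        raise UndefinedStatisticError("no eligible genes")
    return {
        "n_genes": len(first_lens),
        "avg_first_len": float(np.mean(first_lens)),
        "avg_last_len": float(np.mean(last_lens)),
        "pct_te_bp_first": 100.0 * first_te / sum(first_lens),
        "pct_te_bp_last": 100.0 * last_te / sum(last_lens),
    }


def utr_cds_fractions(genes: Sequence[GeneModel]) -> tuple[float, float]:
    """Genome-wide (UTR bp, CDS bp) fractions over exonic bases of the
    supplied gene models (one isoform per gene, longest CDS)."""
    utr_bp = cds_bp = 0
    for gene in longest_cds_isoforms(genes):
        for ex in gene.exons:
            if gene.is_coding:
                c = overlap_bp(
                    ex,
                    type(ex)(ex.chrom, gene.cds_start, gene.cds_end),
                )
            else:
                c = 0
            cds_bp += c
            utr_bp += ex.length() - c
    total = utr_bp + cds_bp
    if total == 0:
        raise UndefinedStatisticError("gene models have no exonic bases")
    return utr_bp / total, cds_bp / total


def utr_cds_enrichment(events, genes) -> StatResult:
    """Goodness-of-fit test of where exonizations land within genes.

    Observed (UTR, CDS) event counts are tested against expected
    proportions equal to the genome-wide UTR:CDS base-pair ratio of the
    gene models (the null: exonizations land uniformly over exonic
    sequence classes).
    """
    gidx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    n_utr = n_cds = 0
    for ev in events:
        placement = ev.gene_placement
        if placement not in ("UTR", "CDS"):
            placement = locate_in_gene(ev, gidx)
        if placement == "UTR":
            n_utr += 1
        elif placement == "CDS":
            n_cds += 1
    if n_utr + n_cds < 1:
        raise UndefinedStatisticError("no events within annotated genes")
    f_utr, f_cds = utr_cds_fractions(gidx.genes)
    return chi2_goodness_of_fit([n_utr, n_cds], [f_utr, f_cds])
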