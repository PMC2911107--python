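"""Independent brute-force oracles used by the tests.

These deliberately re-derive results from per-base set membership and
exhaustive enumeration, not from the package's interval-tree logic.
"""

from __future__ import annotations

import math
from fractions import Fraction


def per_base_overlap(a, b) -> int:
    """Per-base membership count of the intersection of two intervals."""
    if a.chrom != b.chrom:
        return 0
    bases_b = set(range(b.start, b.end))
    return sum(1 for p in range(a.start, a.end) if p in bases_b)


def per_base_union_te_bp(target, intervals) -> int:
    covered = set()
    for iv in intervals:
        if iv.chrom != target.chrom:
            continue
        covered.update(range(iv.start, iv.end))
    return sum(1 for p in range(target.start, target.end) if p in covered)


def oracle_context_label(te, alignments) -> str:
    """Per-base reclassification of one TE against every alignment.

    A simple span check prefilters alignments; every decision about
    block/gap membership and splice-boundary bases is made base by base.
    """
    iv = te.interval
    te_bases = set(range(iv.start, iv.end))
    overlaps_block = overlaps_gap = internal_overlap = site_in_te = False
    for aln in alignments:
        if aln.chrom != iv.chrom:
            continue
        if aln.blocks[-1].end <= iv.start or aln.blocks[0].start >= iv.end:
            continue
        n = len(aln.blocks)
        for bi, b in enumerate(aln.blocks):
            bb = set(range(b.start, b.end))
            if te_bases & bb:
                overlaps_block = True
                if 0 < bi < n - 1:
                    internal_overlap = True
                    if b.start in te_bases or (b.end - 1) in te_bases:
                        site_in_te = True
        for g in aln.introns():
            if te_bases & set(range(g.start, g.end)):
                overlaps_gap = True
    if site_in_te:
        return "exonized"
    if overlaps_block:
        return "exonic_internal_nonspliced" if internal_overlap else "exonic_terminal"
    if overlaps_gap:
        return "intronic"
    return "intergenic"


def oracle_in_refseq(te, genes) -> bool:
    iv = te.interval
    te_bases = set(range(iv.start, iv.end))
    for g in genes:
        if g.chrom == iv.chrom and te_bases & set(range(g.tx_start, g.tx_end)):
            return True
    return False


def oracle_chi2_statistic(table) -> float:
    """Sum of (O-E)^2/E with expected counts from the margins, cell by cell."""
    r = len(table)
    c = len(table[0])
    row_sums = [sum(table[i]) for i in range(r)]
    col_sums = [sum(table[i][j] for i in range(r)) for j in range(c)]
    n = sum(row_sums)
    stat = 0.0
    for i in range(r):
        for j in range(c):
            e = row_sums[i] * col_sums[j] / n
            stat += (table[i][j] - e) ** 2 / e
    return stat


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of every 2x2 table with
    the observed margins, with exact rational table probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(x):
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return None
        num = (
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(n - c1)
        )
        den = (
            math.factorial(n) * math.factorial(x) * math.factorial(y)
            * math.factorial(z) * math.factorial(w)
        )
        return Fraction(num, den)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p is not None and p <= p_obs:
            total += p
    return float(total)
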