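"""Per-intron TE content and intron-length statistics.

Introns here come from gene models (one isoform per gene — the first
annotated one, to avoid redundancy), not from EST gaps; EST-derived
introns are used only for TE context classification.  TE base pairs are
union lengths: overlapping TE copies inside one intron are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .core import (
    GeneModel,
    StatResult,
    TEAnnotation,
    UndefinedStatisticError,
    union_overlap_bp,
)


def first_isoforms(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """One transcript per gene: the first annotated isoform, in input order."""
    seen: set[str] = set()
    out = []
    for g in genes:
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            out.append(g)
    return out


def intron_te_content(
    genes: Sequence[GeneModel], tes: Sequence[TEAnnotation]
) -> pd.DataFrame:
    """Per-intron record: length, TE ids, union TE bp, contains_te flag.

    Columns: gene_id, intron_index, chrom, start, end, length, te_bp,
    contains_te, te_ids (comma-joined).
    """
    trees: dict[str, IntervalTree] = {}
    for ti, te in enumerate(tes):
        trees.setdefault(te.interval.chrom, IntervalTree()).addi(
            te.interval.start, te.interval.end, ti
        )
    rows = []
    for gene in first_isoforms(genes):
        tree = trees.get(gene.chrom)
        for ii, intr in enumerate(gene.introns()):
            hits = sorted(tree.overlap(intr.start, intr.end)) if tree is not None else []
            ivs = [tes[h.data].interval for h in hits]
            te_bp = union_overlap_bp(intr, ivs)
            rows.append(
                (
                    gene.gene_id, ii, gene.chrom, intr.start, intr.end,
                    intr.length(), te_bp, te_bp > 0,
                    ",".join(sorted(tes[h.data].te_id for h in hits)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "intron_index", "chrom", "start", "end",
            "length", "te_bp", "contains_te", "te_ids",
        ],
    )


def intron_summary(records: pd.DataFrame) -> dict[str, float]:
    """Fraction of TE-containing introns and median lengths.

    Medians are midpoint-of-sorted (mean of the central pair for even
    counts).  ``median_len_with_te_minus_te_bp`` is the median of
    (length - TE bp) over TE-containing introns — the residual intron
    size once the inserted TE sequence is subtracted.
    """
    if len(records) == 0:
        raise UndefinedStatisticError("no introns")
    with_te = records[records["contains_te"]]
    without = records[~records["contains_te"]]

    def _median(s):
        return float(s.median()) if len(s) else float("nan")

    return {
        "n_introns": int(len(records)),
        "n_with_te": int(len(with_te)),
        "fraction_with_te": len(with_te) / len(records),
        "median_len_with_te": _median(with_te["length"]),
        "median_len_without_te": _median(without["length"]),
        "median_len_with_te_minus_te_bp": _median(
            with_te["length"] - with_te["te_bp"]
        ),
    }


@dataclass(frozen=True)
class CorrelationResult:
    pearson: StatResult
    spearman: StatResult


def length_fraction_correlation(
    points: Sequence[tuple[float, float]]
) -> CorrelationResult:
    """Correlation between median intron length and TE-containing-intron
    fraction across species/conditions (Pearson r with two-sided p, plus
    Spearman rho)."""
    if len(points) < 3:
        raise UndefinedStatisticError("need >= 3 points for a correlation")
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    pr = sps.pearsonr(xs, ys)
    sr = sps.spearmanr(xs, ys)
    return CorrelationResult(
        pearson=StatResult(float(pr.statistic), float(pr.pvalue), "pearson"),
        spearman=StatResult(float(sr.statistic), float(sr.pvalue), "spearman"),
    )
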