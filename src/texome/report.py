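"""Species-summary assembly: the family x context count matrix.

Rows are the four TE families plus a Total row; columns are the TE
census (total, intronic, intronic split by RefSeq-gene membership) and
the non-redundant exonization counts split the same way.  Derived
percentages are always computed by :func:`pct` over the table's own
counts, reported both unrounded and rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .core import (
    ExonizationEvent,
    GeneModel,
    TEAnnotation,
    TEContext,
    TE_FAMILIES,
    UndefinedStatisticError,
)
from .locate import GeneIndex

SUMMARY_COLUMNS = (
    "total",
    "intronic",
    "intronic_refseq",
    "intronic_nonrefseq",
    "exons_refseq",
    "exons_nonrefseq",
)
SUMMARY_ROWS = TE_FAMILIES + ("Total",)


@dataclass
class SpeciesSummary:
    """The family x context count matrix with its arithmetic invariants:
    the Total row is the column-wise sum of the family rows, and the
    RefSeq/non-RefSeq intronic split sums to the intronic column."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reindex(
            index=list(SUMMARY_ROWS), columns=list(SUMMARY_COLUMNS)
        ).fillna(0).astype(int)
        self.validate()

    def validate(self) -> None:
        t = self.table
        if (t.to_numpy() < 0).any():
            raise ValueError("summary counts must be non-negative")
        fam = t.loc[list(TE_FAMILIES)]
        if not (t.loc["Total"] == fam.sum(axis=0)).all():
            raise ValueError("Total row must equal the column-wise family sum")
        if not (t["intronic_refseq"] + t["intronic_nonrefseq"] == t["intronic"]).all():
            raise ValueError("intronic RefSeq split must sum to the intronic column")

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesSummary) and self.table.equals(other.table)


class Pct(NamedTuple):
    """A percentage, unrounded and rounded half-up to one decimal."""

    value: float
    rounded: float


def pct(numerator: int, denominator: int) -> Pct:
    """100 * numerator / denominator, exact and rounded half-up (1 dp)."""
    if denominator <= 0:
        raise UndefinedStatisticError("percentage undefined for denominator <= 0")
    value = 100.0 * numerator / denominator
    rounded = float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return Pct(value, rounded)


def summarize(
    contexts: Sequence[TEContext],
    events: Sequence[ExonizationEvent],
    tes: Sequence[TEAnnotation],
    genes: Sequence[GeneModel],
) -> SpeciesSummary:
    """Assemble the count matrix from classified TEs and detected events.

    Exon columns count non-redundant events, each attributed to the
    family of the TE contributing the splice site (donor preferred over
    acceptor when the two lie in different TEs); an event counts under
    RefSeq when its exon overlaps an annotated gene span.
    """
    fam_of = {te.te_id: te.rep_family for te in tes}
    table = pd.DataFrame(0, index=list(SUMMARY_ROWS), columns=list(SUMMARY_COLUMNS))
    for ctx in contexts:
        fam = fam_of[ctx.te_id]
        table.loc[fam, "total"] += 1
        if ctx.label == "intronic":
            table.loc[fam, "intronic"] += 1
            col = "intronic_refseq" if ctx.in_refseq_gene else "intronic_nonrefseq"
            table.loc[fam, col] += 1

    gidx = GeneIndex(genes)
    seen: set[tuple] = set()
    for ev in events:
        if ev.key in seen:
            continue
        seen.add(ev.key)
        te_id = ev.donor_te_id or ev.acceptor_te_id or ev.te_ids[0]
        fam = fam_of[te_id]
        in_refseq = bool(gidx.overlapping(ev.exon.chrom, ev.exon.start, ev.exon.end))
        table.loc[fam, "exons_refseq" if in_refseq else "exons_nonrefseq"] += 1

    table.loc["Total"] = table.loc[list(TE_FAMILIES)].sum(axis=0)
    return SpeciesSummary(table)


def exonization_total(summary: SpeciesSummary) -> int:
    """Total non-redundant exonizations (RefSeq + non-RefSeq, Total row)."""
    row = summary.table.loc["Total"]
    return int(row["exons_refseq"] + row["exons_nonrefseq"])


def pattern_tally(events: Sequence[ExonizationEvent]) -> dict[str, int]:
    """Counts of events by splicing pattern (sums to the event count)."""
    tally = {p: 0 for p in ("cassette", "alt5", "alt3", "constitutive", "unclassified")}
    for ev in events:
        tally[ev.pattern] += 1
    return tally
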