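"""Core domain types and interval arithmetic.

All genomic coordinates in this package are 0-based, half-open
(``[start, end)``), the UCSC table convention.  Readers for 1-based
formats normalise on input.

Strand is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).  Unstranded
features are permitted for transposable elements whose orientation is
unknown; they are excluded from orientation statistics but counted
everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

STRANDS = ("+", "-", ".")

#: The four TE classes tallied throughout: short interspersed elements,
#: long interspersed elements, LTR retroelements and DNA transposons.
TE_FAMILIES = ("SINE", "LINE", "LTR", "DNA")

#: Context labels assigned to every TE (a partition).
CONTEXT_LABELS = (
    "intergenic",
    "intronic",
    "exonized",
    "exonic_terminal",
    "exonic_internal_nonspliced",
    "ambiguous",
)

SPLICE_PATTERNS = ("cassette", "alt5", "alt3", "constitutive", "unclassified")

GENE_PLACEMENTS = ("CDS", "UTR", "unannotated")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedAlignmentError(ValueError):
    """A spliced alignment violates its block invariants."""


class MalformedRecordError(ValueError):
    """An input file record cannot be parsed or is internally inconsistent."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class GenerationError(ValueError):
    """A synthetic-genome configuration is infeasible."""


@dataclass(frozen=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on one sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlap_bp(a: GenomeInterval, b: GenomeInterval) -> int:
    """Number of bases shared by two intervals (0 if on different sequences)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_overlap_bp(target: GenomeInterval, others: Iterable[GenomeInterval]) -> int:
    """Bases of *target* covered by the union of *others* (counted once)."""
    segs = []
    for o in others:
        if o.chrom != target.chrom:
            continue
        s, e = max(o.start, target.start), min(o.end, target.end)
        if s < e:
            segs.append((s, e))
    if not segs:
        return 0
    segs.sort()
    total = 0
    cur_s, cur_e = segs[0]
    for s, e in segs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker hit.

    ``consensus_start``/``consensus_end`` locate the genomic hit within the
    repeat family's consensus sequence, stored 0-based half-open in
    consensus-forward orientation regardless of the genomic strand.
    """

    te_id: str
    interval: GenomeInterval
    rep_name: str
    rep_family: str
    consensus_start: Optional[int] = None
    consensus_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rep_family not in TE_FAMILIES:
            raise ValueError(f"unknown TE family {self.rep_family!r}")
        if (
            self.consensus_start is not None
            and self.consensus_end is not None
            and not self.consensus_start < self.consensus_end
        ):
            raise ValueError("consensus_start must be < consensus_end")


@dataclass(frozen=True)
class SplicedAlignment:
    """One EST/cDNA-to-genome alignment as ordered exon blocks.

    Introns are the gaps between consecutive blocks.
    """

    tx_id: str
    source: str  # {EST, mRNA, RefSeq}
    strand: str
    blocks: tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            raise MalformedAlignmentError(f"{self.tx_id}: alignment has no blocks")
        chrom = blocks[0].chrom
        for prev, nxt in zip(blocks, blocks[1:]):
            if nxt.chrom != chrom:
                raise MalformedAlignmentError(
                    f"{self.tx_id}: blocks span multiple sequences"
                )
            if nxt.start < prev.end:
                raise MalformedAlignmentError(
                    f"{self.tx_id}: blocks overlap or are unsorted "
                    f"({prev.end} > {nxt.start})"
                )

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    def introns(self) -> list[GenomeInterval]:
        return introns_of(self)


def introns_of(aln: SplicedAlignment) -> list[GenomeInterval]:
    """Gaps between consecutive blocks, in genomic order.

    Single-block alignments have no introns.  Zero-length gaps cannot occur
    (readers merge abutting blocks on input).
    """
    out = []
    for prev, nxt in zip(aln.blocks, aln.blocks[1:]):
        if nxt.start == prev.end:
            raise MalformedAlignmentError(
                f"{aln.tx_id}: zero-length gap at {prev.end} (blocks not merged)"
            )
        out.append(GenomeInterval(aln.chrom, prev.end, nxt.start, aln.strand))
    return out


@dataclass(frozen=True)
class GeneModel:
    """A gene model with CDS bounds (genePred-style).

    ``cds_start == cds_end`` marks a non-coding transcript.  First/last
    exons are defined in transcript orientation: for a minus-strand gene
    the first exon is the genomically rightmost one.
    """

    gene_id: str
    tx_id: str
    strand: str
    exons: tuple[GenomeInterval, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise MalformedRecordError(f"{self.tx_id}: gene model has no exons")
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(f"{self.tx_id}: gene strand must be +/-")
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start <= prev.end or nxt.chrom != prev.chrom:
                raise MalformedRecordError(f"{self.tx_id}: exons unsorted/overlapping")
        if not self.cds_start <= self.cds_end:
            raise MalformedRecordError(f"{self.tx_id}: cds_start > cds_end")
        if self.is_coding and not (
            exons[0].start <= self.cds_start and self.cds_end <= exons[-1].end
        ):
            raise MalformedRecordError(f"{self.tx_id}: CDS outside exon span")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def tx_start(self) -> int:
        return self.exons[0].start

    @property
    def tx_end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.tx_start, self.tx_end, self.strand)

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    def first_exon(self) -> GenomeInterval:
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def last_exon(self) -> GenomeInterval:
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def introns(self) -> list[GenomeInterval]:
        return [
            GenomeInterval(self.chrom, prev.end, nxt.start, self.strand)
            for prev, nxt in zip(self.exons, self.exons[1:])
        ]

    def cds_len(self) -> int:
        if not self.is_coding:
            return 0
        cds = GenomeInterval(self.chrom, self.cds_start, self.cds_end)
        return sum(overlap_bp(e, cds) for e in self.exons)


@dataclass
class TEContext:
    """Per-TE genomic-context classification with supporting evidence."""

    te_id: str
    label: str
    in_refseq_gene: bool
    evidence_tx: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in CONTEXT_LABELS:
            raise ValueError(f"unknown context label {self.label!r}")


@dataclass
class ExonizationEvent:
    """A TE-derived internal exon with splice-site provenance.

    ``donor_pos``/``acceptor_pos`` are the genomic positions of the exonic
    boundary base adjacent to the donor (5'ss) and acceptor (3'ss) junction.
    ``donor_dinuc``/``acceptor_dinuc`` are the intron-terminal dinucleotides
    read on the transcript strand (canonical: GT / AG).
    """

    exon: GenomeInterval
    te_ids: list[str]
    donor_pos: int
    acceptor_pos: int
    donor_in_te: bool
    acceptor_in_te: bool
    donor_dinuc: str
    acceptor_dinuc: str
    orientation: Optional[str]  # sense / antisense / None (unstranded TE)
    pattern: str = "unclassified"
    gene_placement: str = "unannotated"
    len_mod3: int = -1
    has_stop_in_frame: Optional[bool] = None
    supporting_tx: list[str] = field(default_factory=list)
    donor_te_id: Optional[str] = None
    acceptor_te_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.donor_in_te or self.acceptor_in_te):
            raise ValueError("event must have at least one splice site within a TE")
        if self.len_mod3 == -1:
            self.len_mod3 = self.exon.length() % 3

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Non-redundancy key: exact coordinates plus strand."""
        return (self.exon.chrom, self.exon.start, self.exon.end, self.exon.strand)


@dataclass(frozen=True)
class StatResult:
    """Outcome of one significance test."""

    statistic: float
    p_value: float
    test_name: str
    dof: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
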