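"""Detection and characterisation of TE exonizations.

An exonization is an internal exon block of a spliced alignment that
(i) overlaps at least one TE by >= 1 bp, (ii) is flanked by canonical
splice-site dinucleotides (intron-terminal GT donor / AG acceptor, read
strand-aware), and (iii) has at least one splice-boundary base (the
first or last exonic base) inside a TE's genomic span.  First and last
blocks of an alignment are never considered — a terminal block's outer
edge is an alignment end, not a splice site.

Events sharing exact (chrom, start, end, strand) are collapsed into one
non-redundant event carrying the union of supporting transcripts;
near-duplicates differing by a few bp are deliberately kept separate
(they are genuine alternative-splice-site events).

Splicing-pattern classification (cassette / alternative 5'ss /
alternative 3'ss / constitutive) follows the evidence of alignments that
span the event exon, with the priority cassette > alt5/alt3 >
constitutive when evidence conflicts, and a minimum of two spanning
alignments before an exon may be called constitutive (sparse EST
coverage otherwise inflates constitutive calls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import (
    ExonizationEvent,
    GeneModel,
    GenomeInterval,
    SplicedAlignment,
    STOP_CODONS,
    TEAnnotation,
    overlap_bp,
    revcomp,
)
from .locate import GeneIndex

logger = logging.getLogger(__name__)

CANONICAL_DONOR = ("GT",)
CANONICAL_DONOR_WITH_GC = ("GT", "GC")


def _te_tree(tes: Sequence[TEAnnotation]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ti, te in enumerate(tes):
        trees.setdefault(te.interval.chrom, IntervalTree()).addi(
            te.interval.start, te.interval.end, ti
        )
    return trees


def detect_exonizations(
    tes: Sequence[TEAnnotation],
    alignments: Sequence[SplicedAlignment],
    genome: dict[str, str],
    allow_gc_donor: bool = False,
) -> list[ExonizationEvent]:
    """Scan all internal alignment blocks for TE-derived exons.

    The result is non-redundant (deduplicated on exact exon coordinates
    plus strand) and deterministic: independent of the input order of
    alignments and TEs.
    """
    trees = _te_tree(tes)
    donors = CANONICAL_DONOR_WITH_GC if allow_gc_donor else CANONICAL_DONOR
    events: dict[tuple, ExonizationEvent] = {}

    for aln in sorted(alignments, key=lambda a: a.tx_id):
        if aln.chrom not in genome:
            raise KeyError(f"chromosome {aln.chrom!r} absent from genome FASTA")
        seq = genome[aln.chrom]
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        n = len(aln.blocks)
        for bi in range(1, n - 1):
            b = aln.blocks[bi]
            hits = sorted(tree.overlap(b.start, b.end), key=lambda h: (h.begin, h.end))
            if not hits:
                continue
            left = seq[b.start - 2 : b.start]
            right = seq[b.end : b.end + 2]
            if aln.strand == "+":
                donor_dinuc, acceptor_dinuc = right, left
                donor_base, acceptor_base = b.end - 1, b.start
            else:
                donor_dinuc, acceptor_dinuc = revcomp(left), revcomp(right)
                donor_base, acceptor_base = b.start, b.end - 1
            if donor_dinuc not in donors or acceptor_dinuc != "AG":
                continue
            donor_te = acceptor_te = None
            for h in hits:
                te = tes[h.data]
                if donor_te is None and te.interval.contains(donor_base):
                    donor_te = te
                if acceptor_te is None and te.interval.contains(acceptor_base):
                    acceptor_te = te
            if donor_te is None and acceptor_te is None:
                continue
            key = (aln.chrom, b.start, b.end, aln.strand)
            if key in events:
                ev = events[key]
                if aln.tx_id not in ev.supporting_tx:
                    ev.supporting_tx.append(aln.tx_id)
                for h in hits:
                    tid = tes[h.data].te_id
                    if tid not in ev.te_ids:
                        ev.te_ids.append(tid)
                ev.te_ids.sort()
                continue
            site_te = donor_te or acceptor_te
            orient = (
                None
                if site_te.interval.strand == "."
                else ("sense" if site_te.interval.strand == aln.strand else "antisense")
            )
            events[key] = ExonizationEvent(
                exon=GenomeInterval(aln.chrom, b.start, b.end, aln.strand),
                te_ids=sorted(tes[h.data].te_id for h in hits),
                donor_pos=donor_base,
                acceptor_pos=acceptor_base,
                donor_in_te=donor_te is not None,
                acceptor_in_te=acceptor_te is not None,
                donor_dinuc=donor_dinuc,
                acceptor_dinuc=acceptor_dinuc,
                orientation=orient,
                supporting_tx=[aln.tx_id],
                donor_te_id=donor_te.te_id if donor_te else None,
                acceptor_te_id=acceptor_te.te_id if acceptor_te else None,
            )
    for ev in events.values():
        ev.supporting_tx.sort()
    return [events[k] for k in sorted(events)]


def classify_splice_pattern(
    event: ExonizationEvent, alignments: Sequence[SplicedAlignment]
) -> str:
    """Classify an event from spanning-alignment evidence.

    cassette: some spanning alignment splices flank-to-flank over the
    exon; alt5/alt3: another alignment's exon shares one boundary and
    shifts the other (donor for alt5, acceptor for alt3, strand-aware);
    constitutive: >= 2 spanning alignments, all of which include the exon
    with identical boundaries.  When both alternative-site kinds occur,
    the rarer one (fewest supporting alignments, ties to alt5) is
    reported.
    """
    exon = event.exon
    strand = exon.strand
    spanning = []
    for aln in alignments:
        if aln.chrom != exon.chrom or aln.strand != strand:
            continue
        if aln.blocks[0].end <= exon.start and aln.blocks[-1].start >= exon.end:
            spanning.append(aln)

    cassette = any(
        g.start <= exon.start and g.end >= exon.end
        for aln in spanning
        for g in aln.introns()
    )
    if cassette:
        return "cassette"

    alt5 = alt3 = 0
    for aln in alignments:
        if aln.chrom != exon.chrom or aln.strand != strand:
            continue
        hit5 = hit3 = False
        for b in aln.blocks:
            if b.start == exon.start and b.end != exon.end:
                hit5 = hit5 or strand == "+"
                hit3 = hit3 or strand == "-"
            if b.end == exon.end and b.start != exon.start:
                hit3 = hit3 or strand == "+"
                hit5 = hit5 or strand == "-"
        alt5 += hit5
        alt3 += hit3
    if alt5 and alt3:
        return "alt5" if alt5 <= alt3 else "alt3"
    if alt5:
        return "alt5"
    if alt3:
        return "alt3"

    if len(spanning) >= 2 and all(
        any(b.start == exon.start and b.end == exon.end for b in aln.blocks)
        for aln in spanning
    ):
        return "constitutive"
    return "unclassified"


def locate_in_gene(event: ExonizationEvent, genes) -> str:
    """CDS if the exon overlaps the coding span of a same-strand gene,
    UTR if it only overlaps the gene otherwise, else unannotated."""
    gidx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    exon = event.exon
    in_gene = False
    for g in gidx.overlapping(exon.chrom, exon.start, exon.end):
        if g.strand != exon.strand:
            continue
        in_gene = True
        if g.is_coding and min(exon.end, g.cds_end) > max(exon.start, g.cds_start):
            return "CDS"
    return "UTR" if in_gene else "unannotated"


def frame_analysis(
    event: ExonizationEvent, genes, genome: dict[str, str]
) -> tuple[int, Optional[bool]]:
    """(exon length mod 3, in-frame stop?) for a CDS-placed event.

    The reading frame is inherited from the coding exons transcript-
    upstream of the insertion point; codons fully inside the new exon are
    scanned for TAA/TAG/TGA.  For non-CDS events the stop flag is
    undefined (``None``).
    """
    gidx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    exon = event.exon
    mod3 = exon.length() % 3
    host = None
    for g in gidx.overlapping(exon.chrom, exon.start, exon.end):
        if (
            g.strand == exon.strand
            and g.is_coding
            and min(exon.end, g.cds_end) > max(exon.start, g.cds_start)
        ):
            host = g
            break
    if host is None:
        return mod3, None
    cds = GenomeInterval(host.chrom, host.cds_start, host.cds_end)
    if host.strand == "+":
        cum = sum(overlap_bp(e, cds) for e in host.exons if e.end <= exon.start)
        eseq = genome[exon.chrom][exon.start : exon.end]
    else:
        cum = sum(overlap_bp(e, cds) for e in host.exons if e.start >= exon.end)
        eseq = revcomp(genome[exon.chrom][exon.start : exon.end])
    off = (3 - cum % 3) % 3
    has_stop = any(
        eseq[i : i + 3] in STOP_CODONS for i in range(off, len(eseq) - 2, 3)
    )
    return mod3, has_stop


def annotate_events(
    events: Sequence[ExonizationEvent],
    alignments: Sequence[SplicedAlignment],
    genes: Sequence[GeneModel],
    genome: dict[str, str],
) -> list[ExonizationEvent]:
    """Fill pattern, gene placement and frame fields of detected events."""
    gidx = GeneIndex(genes)
    for ev in events:
        ev.pattern = classify_splice_pattern(ev, alignments)
        ev.gene_placement = locate_in_gene(ev, gidx)
        mod3, has_stop = frame_analysis(ev, gidx, genome)
        ev.len_mod3 = mod3
        ev.has_stop_in_frame = has_stop if ev.gene_placement == "CDS" else None
    return list(events)


@dataclass(frozen=True)
class InternalCDSInsertion:
    """A TE fully inside an internal coding exon, in-frame and stop-free."""

    te_id: str
    gene_id: str
    tx_id: str
    exon: GenomeInterval
    te_interval: GenomeInterval
    upstream_intron_len: int
    downstream_intron_len: int

    @property
    def te_len(self) -> int:
        return self.te_interval.length()


def detect_internal_cds_insertions(
    tes: Sequence[TEAnnotation],
    genes: Sequence[GeneModel],
    genome: dict[str, str],
) -> list[InternalCDSInsertion]:
    """TEs fully contained within internal CDS exons whose length is a
    multiple of three and which carry no in-frame stop codon, i.e.
    insertions that extend the protein without disrupting it.  Flanking
    intron lengths (transcript orientation) are reported alongside."""
    trees = _te_tree(tes)
    out: list[InternalCDSInsertion] = []
    for gene in genes:
        if not gene.is_coding or len(gene.exons) < 3:
            continue
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        seq = genome[gene.chrom]
        cds = GenomeInterval(gene.chrom, gene.cds_start, gene.cds_end)
        introns = gene.introns()
        for k in range(1, len(gene.exons) - 1):
            exon = gene.exons[k]
            lo = max(exon.start, gene.cds_start)
            hi = min(exon.end, gene.cds_end)
            if hi <= lo:
                continue
            if gene.strand == "+":
                cum = sum(overlap_bp(e, cds) for e in gene.exons if e.end <= exon.start)
                up_len, down_len = introns[k - 1].length(), introns[k].length()
            else:
                cum = sum(overlap_bp(e, cds) for e in gene.exons if e.start >= exon.end)
                up_len, down_len = introns[k].length(), introns[k - 1].length()
            off = (3 - cum % 3) % 3
            for h in sorted(tree.overlap(lo, hi), key=lambda h: (h.begin, h.end)):
                te = tes[h.data]
                ts, te_end = te.interval.start, te.interval.end
                if ts < lo or te_end > hi:
                    continue
                if te.interval.length() % 3 != 0:
                    continue
                if _te_has_stop(seq, gene.strand, exon, off, ts, te_end):
                    continue
                out.append(
                    InternalCDSInsertion(
                        te_id=te.te_id, gene_id=gene.gene_id, tx_id=gene.tx_id,
                        exon=exon, te_interval=te.interval,
                        upstream_intron_len=up_len, downstream_intron_len=down_len,
                    )
                )
    return out


def _te_has_stop(
    seq: str, strand: str, exon: GenomeInterval, off: int, ts: int, te_end: int
) -> bool:
    """Does any codon of the exon's reading frame fully inside [ts, te_end)
    spell a stop (read on the transcript strand)?"""
    if strand == "+":
        for p in range(exon.start + off, exon.end - 2, 3):
            if p >= ts and p + 3 <= te_end:
                if seq[p : p + 3] in STOP_CODONS:
                    return True
    else:
        # transcript offset t corresponds to genomic base exon.end-1-t
        for t in range(off, exon.length() - 2, 3):
            g_end = exon.end - t
            g_start = g_end - 3
            if g_start >= ts and g_end <= te_end:
                if revcomp(seq[g_start:g_end]) in STOP_CODONS:
                    return True
    return False


def consensus_splice_profile(
    events: Sequence[ExonizationEvent], tes: Sequence[TEAnnotation]
) -> pd.DataFrame:
    """Usage counts of donor/acceptor sites in repeat-consensus coordinates.

    Each event's donor and acceptor genomic position is mapped into the
    consensus of the contributing TE by linear interpolation between
    (genomic start <-> consensus_start) and (genomic end <-> consensus_end),
    reversed for minus-strand TEs.  Sites falling outside the TE span are
    recorded at consensus position -1 ("outside" bin).  Events whose TE
    lacks consensus coordinates are skipped with a warning.

    Returns a table with columns consensus_pos, site, orientation, count.
    """
    by_id = {te.te_id: te for te in tes}
    rows = []
    for ev in events:
        ref5 = ev.donor_te_id or ev.acceptor_te_id
        ref3 = ev.acceptor_te_id or ev.donor_te_id
        orient = ev.orientation or "undefined"
        for site, pos, ref in (("donor", ev.donor_pos, ref5), ("acceptor", ev.acceptor_pos, ref3)):
            te = by_id.get(ref)
            if te is None or te.consensus_start is None or te.consensus_end is None:
                logger.warning(
                    "event %s:%d-%d: no consensus coordinates, skipped",
                    ev.exon.chrom, ev.exon.start, ev.exon.end,
                )
                continue
            rows.append((_to_consensus(te, pos), site, orient))
    df = pd.DataFrame(rows, columns=["consensus_pos", "site", "orientation"])
    return (
        df.groupby(["consensus_pos", "site", "orientation"])
        .size()
        .reset_index(name="count")
        .sort_values(["site", "consensus_pos", "orientation"], ignore_index=True)
    )


def _to_consensus(te: TEAnnotation, pos: int) -> int:
    s, e = te.interval.start, te.interval.end
    cs, ce = te.consensus_start, te.consensus_end
    if pos < s or pos >= e:
        return -1
    if e - s == 1:
        return cs
    scale = (ce - cs - 1) / (e - s - 1)
    if te.interval.strand == "-":
        return cs + round((e - 1 - pos) * scale)
    return cs + round((pos - s) * scale)
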