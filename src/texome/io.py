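"""Readers and writers for the standard annotation formats.

Dialects handled:

* RepeatMasker ``.out`` (3-line header, 1-based inclusive genomic
  coordinates, strand ``C`` for minus hits) and the UCSC ``rmsk``
  tab-separated table (0-based half-open).
* BED12 and PSL spliced alignments (both normalised to the same
  :class:`~texome.core.SplicedAlignment`).
* genePred gene models.
* FASTA genomes (via Biopython; sequences are uppercased on read).
* The family x context summary table as TSV.

All coordinates are normalised to 0-based half-open on read, so the same
logical content read through different dialects compares bit-equal.
Consensus coordinates are stored consensus-forward (0-based half-open)
for both strands.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    GeneModel,
    GenomeInterval,
    MalformedRecordError,
    SplicedAlignment,
    TEAnnotation,
    TE_FAMILIES,
)

logger = logging.getLogger(__name__)

#: repClass strings mapped to the four tallied families.  A repClass like
#: "LINE/CR1" maps through its top-level component.  Anything else
#: (Simple_repeat, Low_complexity, Satellite, ...) is not a TE here and the
#: row is skipped (counted and logged).
_REPCLASS_MAP = {
    "SINE": "SINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "DNA": "DNA",
}

_RMSK_TAB_COLUMNS = [
    "bin", "swScore", "milliDiv", "milliDel", "milliIns",
    "genoName", "genoStart", "genoEnd", "genoLeft", "strand",
    "repName", "repClass", "repFamily", "repStart", "repEnd", "repLeft", "id",
]


def _map_repclass(rep_class: str) -> str | None:
    return _REPCLASS_MAP.get(rep_class.split("/", 1)[0])


def read_te_annotations(path, dialect: str) -> list[TEAnnotation]:
    """Read TE annotations from a RepeatMasker ``.out`` or UCSC rmsk table.

    Rows whose repClass does not map to SINE/LINE/LTR/DNA are skipped; the
    skip count is logged at WARNING level.
    """
    if dialect == "rmsk_tab":
        return _read_rmsk_tab(path)
    if dialect == "rmsk_out":
        return _read_rmsk_out(path)
    raise ValueError(f"unknown TE annotation dialect {dialect!r}")


def _read_rmsk_tab(path) -> list[TEAnnotation]:
    out: list[TEAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == len(_RMSK_TAB_COLUMNS) - 1:
                # dumps without the leading UCSC bin column
                fields = ["0"] + fields
            if len(fields) != len(_RMSK_TAB_COLUMNS):
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected {len(_RMSK_TAB_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            row = dict(zip(_RMSK_TAB_COLUMNS, fields))
            family = _map_repclass(row["repClass"])
            if family is None:
                skipped += 1
                continue
            try:
                interval = GenomeInterval(
                    row["genoName"], int(row["genoStart"]), int(row["genoEnd"]),
                    row["strand"] if row["strand"] in ("+", "-") else ".",
                )
                cs, ce = int(row["repStart"]), int(row["repEnd"])
            except ValueError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
            out.append(
                TEAnnotation(
                    te_id=f"{row['repName']}|{row['genoName']}:"
                    f"{row['genoStart']}-{row['genoEnd']}",
                    interval=interval,
                    rep_name=row["repName"],
                    rep_family=family,
                    consensus_start=cs if cs >= 0 else None,
                    consensus_end=ce if cs >= 0 else None,
                )
            )
    if skipped:
        logger.warning("%s: skipped %d non-TE repeat rows", path, skipped)
    return out


def _read_rmsk_out(path) -> list[TEAnnotation]:
    """RepeatMasker .out: whitespace-separated, 3-line header, 1-based
    inclusive genomic coordinates; minus hits are flagged ``C`` and report
    consensus fields in (left) end begin order."""
    out: list[TEAnnotation] = []
    skipped = 0
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], 4):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 14:
            raise MalformedRecordError(f"{path}:{lineno}: too few columns")
        family = _map_repclass(f[10])
        if family is None:
            skipped += 1
            continue
        try:
            start, end = int(f[5]) - 1, int(f[6])  # 1-based inclusive -> half-open
            strand = "+" if f[8] == "+" else "-"
            if strand == "+":
                cons_begin, cons_end = int(f[11]), int(f[12])
            else:
                # columns: (left) end begin -> consensus-forward span
                cons_begin, cons_end = int(f[13]), int(f[12])
            interval = GenomeInterval(f[4], start, end, strand)
        except ValueError as exc:
            raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
        out.append(
            TEAnnotation(
                te_id=f"{f[9]}|{f[4]}:{start}-{end}",
                interval=interval,
                rep_name=f[9],
                rep_family=family,
                consensus_start=cons_begin - 1,
                consensus_end=cons_end,
            )
        )
    if skipped:
        logger.warning("%s: skipped %d non-TE repeat rows", path, skipped)
    return out


def write_rmsk_tab(tes: Sequence[TEAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_RMSK_TAB_COLUMNS) + "\n")
        for te in tes:
            iv = te.interval
            cs = te.consensus_start if te.consensus_start is not None else -1
            ce = te.consensus_end if te.consensus_end is not None else -1
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        0, 0, 0, 0, 0,
                        iv.chrom, iv.start, iv.end, 0,
                        iv.strand if iv.strand in ("+", "-") else "+",
                        te.rep_name, f"{te.rep_family}/{te.rep_name}",
                        te.rep_name, cs, ce, 0, 0,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Spliced alignments


def read_spliced_alignments(path, dialect: str, source: str = "EST") -> list[SplicedAlignment]:
    """Read spliced alignments from BED12 or PSL.

    PSL target coordinates are used; abutting blocks (zero-length gap) are
    merged in both dialects.
    """
    if dialect == "bed12":
        return _read_bed12(path, source)
    if dialect == "psl":
        return _read_psl(path, source)
    raise ValueError(f"unknown spliced-alignment dialect {dialect!r}")


def _merge_abutting(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _read_bed12(path, source: str) -> list[SplicedAlignment]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise MalformedRecordError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            n = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != n or len(starts) != n:
                raise MalformedRecordError(
                    f"{path}:{lineno}: blockCount {n} does not match block lists"
                )
            raw = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
            blocks = tuple(
                GenomeInterval(chrom, s, e, strand) for s, e in _merge_abutting(raw)
            )
            out.append(SplicedAlignment(name, source, strand, blocks))
    return out


def _read_psl(path, source: str) -> list[SplicedAlignment]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            f = line.split("\t")
            if len(f) < 21:
                raise MalformedRecordError(f"{path}:{lineno}: PSL needs 21 columns")
            strand = f[8][0]
            name, target = f[9], f[13]
            n = int(f[17])
            sizes = [int(x) for x in f[18].rstrip(",").split(",") if x]
            tstarts = [int(x) for x in f[20].rstrip(",").split(",") if x]
            if len(sizes) != n or len(tstarts) != n:
                raise MalformedRecordError(
                    f"{path}:{lineno}: blockCount {n} does not match block lists"
                )
            raw = [(ts, ts + sz) for ts, sz in zip(tstarts, sizes)]
            blocks = tuple(
                GenomeInterval(target, s, e, strand) for s, e in _merge_abutting(raw)
            )
            out.append(SplicedAlignment(name, source, strand, blocks))
    return out


def write_bed12(alignments: Sequence[SplicedAlignment], path) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            start = aln.blocks[0].start
            end = aln.blocks[-1].end
            sizes = ",".join(str(b.length()) for b in aln.blocks) + ","
            starts = ",".join(str(b.start - start) for b in aln.blocks) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        aln.chrom, start, end, aln.tx_id, 0, aln.strand,
                        start, start, 0, len(aln.blocks), sizes, starts,
                    ]
                )
                + "\n"
            )


def write_psl(alignments: Sequence[SplicedAlignment], path, target_size: int = 0) -> None:
    """Minimal PSL writer (match counts zeroed; block structure exact)."""
    with open(path, "w") as fh:
        for aln in alignments:
            qsize = sum(b.length() for b in aln.blocks)
            sizes = ",".join(str(b.length()) for b in aln.blocks) + ","
            qstarts = []
            q = 0
            for b in aln.blocks:
                qstarts.append(q)
                q += b.length()
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        qsize, 0, 0, 0, 0, 0, 0, 0, aln.strand,
                        aln.tx_id, qsize, 0, qsize,
                        aln.chrom, target_size,
                        aln.blocks[0].start, aln.blocks[-1].end,
                        len(aln.blocks), sizes,
                        ",".join(str(s) for s in qstarts) + ",",
                        ",".join(str(b.start) for b in aln.blocks) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models


def read_gene_models(path) -> list[GeneModel]:
    """Read genePred gene models (name chrom strand txStart txEnd cdsStart
    cdsEnd exonCount exonStarts exonEnds [...])."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise MalformedRecordError(f"{path}:{lineno}: genePred needs >= 10 columns")
            name, chrom, strand = f[0], f[1], f[2]
            cds_start, cds_end = int(f[5]), int(f[6])
            n = int(f[7])
            starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
            if len(starts) != n or len(ends) != n:
                raise MalformedRecordError(f"{path}:{lineno}: exonCount mismatch")
            exons = tuple(
                GenomeInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
            )
            gene_id = f[11] if len(f) > 11 and f[11] else name
            try:
                out.append(
                    GeneModel(
                        gene_id=gene_id, tx_id=name, strand=strand,
                        exons=exons, cds_start=cds_start, cds_end=cds_end,
                    )
                )
            except MalformedRecordError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_genepred(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        g.tx_id, g.chrom, g.strand, g.tx_start, g.tx_end,
                        g.cds_start, g.cds_end, len(g.exons),
                        ",".join(str(e.start) for e in g.exons) + ",",
                        ",".join(str(e.end) for e in g.exons) + ",",
                        0, g.gene_id,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genome FASTA


def read_genome(path) -> dict[str, str]:
    """Read a FASTA genome into {name: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise MalformedRecordError(f"{path}: duplicate FASTA id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_genome(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Summary table


def write_summary_tsv(table: pd.DataFrame, path) -> None:
    """Write the family x context count matrix with a header row."""
    table.to_csv(path, sep="\t", index=True, index_label="family")


def read_summary_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="family")
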