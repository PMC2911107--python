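"""Synthetic genomes with planted ground truth.

The generator emits a single-chromosome genome (FASTA), RepeatMasker-style
TE annotations (rmsk tab), gene models (genePred) and sampled EST
alignments (BED12), together with a :class:`TruthRecord` giving the true
context label of every TE, every planted exonization with its splicing
pattern, per-intron TE content and per-terminal-exon TE base pairs.

What is emulated
----------------
* multi-exon genes separated by intergenic spacers, with configurable
  exon-count, exon-length and (lognormal) intron-length distributions —
  presets cover short-intron ("fly-like", median 72 bp), mid
  ("worm-like", median ~700 bp) and long-intron ("vertebrate-like",
  median ~3 kb) architectures;
* TE insertions of the four families (SINE/LINE/LTR/DNA) at configurable
  per-kb densities, with per-family antisense-insertion probabilities;
* exonizations: an intronic TE is recruited as an internal exon with
  canonical GT–AG splice sites written into the sequence inside the TE's
  genomic span; the splicing pattern (cassette / alt 5'ss / alt 3'ss /
  constitutive) is planted by controlling which isoform each sampled EST
  carries;
* TE insertions into first/last (largely UTR) exons, and in-frame,
  stop-free (or deliberately stop-containing) TE insertions fully inside
  internal coding exons;
* EST sampling at configurable depth, optionally truncated at a random
  5' start so that first/last-block exclusion logic is exercised.

Background sequence is i.i.d. uniform ACGT: the downstream analysis uses
sequence only for splice-site dinucleotides and stop codons, both of
which are planted explicitly.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    GeneModel,
    GenomeInterval,
    GenerationError,
    SplicedAlignment,
    TEAnnotation,
    TE_FAMILIES,
    union_overlap_bp,
)
from . import io as fio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_INTRON_PRESETS = {
    "fly-like": 72.0,
    "worm-like": 700.0,
    "vertebrate-like": 3000.0,
}


def _default_density() -> dict[str, float]:
    return {"SINE": 0.8, "LINE": 0.5, "LTR": 0.3, "DNA": 0.5}


def _default_te_len() -> dict[str, tuple[int, int]]:
    return {"SINE": (60, 160), "LINE": (80, 300), "LTR": (80, 250), "DNA": (60, 200)}


def _default_antisense() -> dict[str, float]:
    # LTRs (and to a lesser extent LINEs) fix preferentially antisense to
    # the host transcript; SINEs and DNA transposons show no strong bias.
    return {"SINE": 0.5, "LINE": 0.6, "LTR": 0.7, "DNA": 0.5}


def _default_pattern_mix() -> dict[str, float]:
    return {"cassette": 0.5, "alt5": 0.2, "alt3": 0.2, "constitutive": 0.1}


def _default_consensus_len() -> dict[str, int]:
    # SINE length mirrors the 402-bp tRNA-derived HE1 consensus.
    return {"SINE": 402, "LINE": 5000, "LTR": 3000, "DNA": 1500}


@dataclass
class SimConfig:
    """Parameters of one synthetic genome."""

    seed: int = 0
    chrom: str = "chr1"
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (80, 220)
    intron_len_median: float = 700.0
    intron_len_sigma: float = 0.6
    intergenic_spacer: int = 1500
    te_density_per_family: dict[str, float] = field(default_factory=_default_density)
    te_len: dict[str, tuple[int, int]] = field(default_factory=_default_te_len)
    p_antisense_per_family: dict[str, float] = field(default_factory=_default_antisense)
    p_unstranded: float = 0.0
    p_exonization: float = 0.05
    exonization_pattern_mix: dict[str, float] = field(default_factory=_default_pattern_mix)
    est_depth: int = 10
    p_truncate: float = 0.2
    p_first_last_te: float = 0.1
    utr_len: tuple[int, int] = (40, 150)
    p_utr_intron: float = 0.25  # chance a terminal UTR extends past the terminal exon
    n_internal_cds_te: int = 0
    n_internal_cds_te_disqualified: int = 0
    consensus_len: dict[str, int] = field(default_factory=_default_consensus_len)

    def __post_init__(self) -> None:
        probs = [
            self.p_unstranded, self.p_exonization, self.p_truncate,
            self.p_first_last_te, self.p_utr_intron,
            *self.p_antisense_per_family.values(),
            *self.exonization_pattern_mix.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise GenerationError("all probabilities must lie in [0, 1]")
        if abs(sum(self.exonization_pattern_mix.values()) - 1.0) > 1e-9:
            raise GenerationError("exonization_pattern_mix must sum to 1")
        if self.est_depth < 1:
            raise GenerationError("est_depth must be >= 1")
        for lo, hi in (self.exons_per_gene, self.exon_len, self.utr_len):
            if not 0 < lo <= hi:
                raise GenerationError("distribution bounds must satisfy 0 < lo <= hi")
        if self.exons_per_gene[0] < 2:
            raise GenerationError("genes need at least 2 exons")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimConfig":
        """A config whose intron-length distribution matches a named
        architecture: 'fly-like' (median 72 bp), 'worm-like' (~700 bp) or
        'vertebrate-like' (~3 kb)."""
        if name not in _INTRON_PRESETS:
            raise GenerationError(f"unknown preset {name!r}")
        return cls(intron_len_median=_INTRON_PRESETS[name], **overrides)


@dataclass
class TruthEvent:
    """One planted exonized exon (one isoform's boundaries)."""

    chrom: str
    start: int
    end: int
    strand: str
    pattern: str
    te_id: str
    donor_pos: int
    acceptor_pos: int
    orientation: Optional[str]
    host_gene: str
    placement: str  # CDS / UTR
    has_stop_in_frame: Optional[bool] = None

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class TruthRecord:
    """Ground truth for one generated genome."""

    labels: dict[str, str] = field(default_factory=dict)
    in_refseq: dict[str, bool] = field(default_factory=dict)
    orientation: dict[str, Optional[str]] = field(default_factory=dict)
    events: list[TruthEvent] = field(default_factory=list)
    intron_records: list[dict] = field(default_factory=list)
    terminal_records: dict[str, dict] = field(default_factory=dict)
    internal_cds: list[tuple[str, bool]] = field(default_factory=list)


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    tes: list[TEAnnotation]
    genes: list[GeneModel]
    alignments: list[SplicedAlignment]
    truth: TruthRecord


@dataclass
class _PlantedEvent:
    # generator-internal bookkeeping for one exonization
    gene_idx: int
    intron_idx: int
    pattern: str
    primary: tuple[int, int]
    alt: Optional[tuple[int, int]]  # second isoform's exon, for alt5/alt3


def _set(seq: np.ndarray, pos: int, s: str) -> None:
    seq[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


def _cum_cds_before(gene: GeneModel, pos: int) -> int:
    """Coding bases in plus-strand transcript order strictly upstream of
    *pos* (which must lie outside the exons or at an exon boundary)."""
    cds = range(gene.cds_start, gene.cds_end)
    total = 0
    for ex in gene.exons:
        if ex.end <= pos:
            total += max(0, min(ex.end, gene.cds_end) - max(ex.start, gene.cds_start))
    return total


def _frame_offset_plus(gene: GeneModel, exon_start: int) -> int:
    """Offset into a plus-strand region at *exon_start* where the next full
    codon begins, given the frame inherited from upstream coding exons."""
    cum = _cum_cds_before(gene, exon_start)
    return (3 - cum % 3) % 3


def generate(config: SimConfig) -> SimResult:
    """Generate one synthetic genome with planted truth (deterministic in
    ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    truth = TruthRecord()

    # ----- gene layout -------------------------------------------------
    genes: list[GeneModel] = []
    spacers: list[tuple[int, int]] = []
    cursor = 0
    for gi in range(config.n_genes):
        spacer = config.intergenic_spacer + int(rng.integers(0, 500))
        spacers.append((cursor, cursor + spacer))
        cursor += spacer
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, size=n_ex)
        in_lens = np.maximum(
            20,
            np.rint(
                rng.lognormal(
                    math.log(config.intron_len_median), config.intron_len_sigma,
                    size=n_ex - 1,
                )
            ).astype(int),
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for k in range(n_ex):
            exons.append(GenomeInterval(config.chrom, pos, pos + int(ex_lens[k]), strand))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        cursor = pos
        # CDS bounds: usually inside the terminal exons; occasionally the
        # UTR spans the terminal intron so some introns are UTR-hosted.
        u5 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
        u3 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
        left_ex = 1 if (n_ex > 2 and rng.random() < config.p_utr_intron) else 0
        right_ex = 1 if (n_ex > 2 and rng.random() < config.p_utr_intron) else 0
        lx, rx = exons[left_ex], exons[-1 - right_ex]
        cds_start = min(lx.start + min(u5, lx.length() - 10), rx.end - 20)
        cds_end = max(rx.end - min(u3, rx.length() - 10), cds_start + 10)
        genes.append(
            GeneModel(
                gene_id=f"gene{gi:04d}", tx_id=f"tx{gi:04d}", strand=strand,
                exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
            )
        )
    final_spacer = config.intergenic_spacer + int(rng.integers(0, 500))
    spacers.append((cursor, cursor + final_spacer))
    genome_len = cursor + final_spacer

    seq = _BASES[rng.integers(0, 4, size=genome_len)]

    # gene splice sites: donor GT / acceptor AG on the transcript strand
    for gene in genes:
        for intr in gene.introns():
            if gene.strand == "+":
                _set(seq, intr.start, "GT")
                _set(seq, intr.end - 2, "AG")
            else:
                _set(seq, intr.start, "CT")
                _set(seq, intr.end - 2, "AC")

    # ----- TE placement ------------------------------------------------
    # regions: intergenic spacers and gene introns
    regions: list[tuple[int, int, str, Optional[int], Optional[int]]] = []
    for s, e in spacers:
        regions.append((s, e, "intergenic", None, None))
    for gi, gene in enumerate(genes):
        for ii, intr in enumerate(gene.introns()):
            regions.append((intr.start, intr.end, "intronic", gi, ii))

    for fam in TE_FAMILIES:
        if config.te_density_per_family.get(fam, 0.0) <= 0:
            continue
        min_len = config.te_len[fam][0]
        if not any(e - s >= min_len + 16 for s, e, *_ in regions):
            raise GenerationError(
                f"no region can host a {fam} TE: te_len >= region length everywhere"
            )

    tes: list[TEAnnotation] = []
    te_meta: dict[str, dict] = {}  # te_id -> {kind, gene_idx, intron_idx}
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(regions))}
    te_counter = 0
    for ri, (rs, re, kind, gi, ii) in enumerate(regions):
        margin = 8 if kind == "intronic" else 2
        for fam in TE_FAMILIES:
            density = config.te_density_per_family.get(fam, 0.0)
            if density <= 0:
                continue
            k = rng.poisson(density * (re - rs) / 1000.0)
            for _ in range(int(k)):
                tl = int(rng.integers(config.te_len[fam][0], config.te_len[fam][1] + 1))
                lo, hi = rs + margin, re - margin - tl
                if hi < lo:
                    continue
                placed = None
                for _try in range(10):
                    start = int(rng.integers(lo, hi + 1))
                    end = start + tl
                    if all(end <= s or start >= e for s, e in occupied[ri]):
                        placed = (start, end)
                        break
                if placed is None:
                    continue
                occupied[ri].append(placed)
                if rng.random() < config.p_unstranded:
                    strand = "."
                elif kind == "intronic":
                    anti = rng.random() < config.p_antisense_per_family.get(fam, 0.5)
                    gstrand = genes[gi].strand
                    strand = ("-" if gstrand == "+" else "+") if anti else gstrand
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                clen = config.consensus_len[fam]
                cs = int(rng.integers(0, max(1, clen - tl + 1)))
                te_id = f"te{te_counter:05d}"
                te_counter += 1
                tes.append(
                    TEAnnotation(
                        te_id=te_id,
                        interval=GenomeInterval(config.chrom, placed[0], placed[1], strand),
                        rep_name=f"{fam}_sim",
                        rep_family=fam,
                        consensus_start=cs,
                        consensus_end=cs + tl,
                    )
                )
                te_meta[te_id] = {"kind": kind, "gene_idx": gi, "intron_idx": ii}

    # ----- exonizations ------------------------------------------------
    patterns = list(config.exonization_pattern_mix)
    pattern_p = np.array([config.exonization_pattern_mix[p] for p in patterns])
    used_introns: set[tuple[int, int]] = set()
    planted: list[_PlantedEvent] = []
    for te in tes:
        meta = te_meta[te.te_id]
        if meta["kind"] != "intronic" or rng.random() >= config.p_exonization:
            continue
        gi, ii = meta["gene_idx"], meta["intron_idx"]
        if (gi, ii) in used_introns:
            continue
        gene = genes[gi]
        intr = gene.introns()[ii]
        ts, te_end = te.interval.start, te.interval.end
        tl = te.interval.length()
        if tl < 40:
            continue
        max_ex = min(150, tl - 10)
        if max_ex < 24:
            continue
        ex_len = int(rng.integers(24, max_ex + 1))
        dx = int(rng.integers(0, tl - ex_len + 1))
        x, y = ts + dx, ts + dx + ex_len
        # both sub-introns must hold their own dinucleotides clear of the
        # host intron's existing splice sites
        if x - intr.start < 4 or intr.end - y < 4:
            continue
        used_introns.add((gi, ii))
        pattern = str(rng.choice(patterns, p=pattern_p))
        if config.est_depth < 2 and pattern != "constitutive":
            pattern = "cassette"  # single-EST sampling cannot carry two isoforms

        alt: Optional[tuple[int, int]] = None
        if pattern in ("alt5", "alt3"):
            # shift the donor (alt5) or acceptor (alt3) boundary; donor is
            # the 3' exon edge for + genes and the 5' edge for - genes
            shift_donor = (pattern == "alt5") == (gene.strand == "+")
            for d in rng.permutation([6, 9, 12, -6, -9, -12]):
                d = int(d)
                if shift_donor:
                    x2, y2 = x, y + d
                else:
                    x2, y2 = x + d, y
                if (
                    x2 >= ts and y2 <= te_end and y2 - x2 >= 12
                    and x2 - intr.start >= 4 and intr.end - y2 >= 4
                ):
                    alt = (x2, y2)
                    break
            if alt is None:
                pattern = "cassette"

        in_cds = gene.cds_start <= x and y <= gene.cds_end
        has_stop: Optional[bool] = None
        if gene.strand == "+" and in_cds and pattern in ("cassette", "constitutive"):
            # control the in-frame stop content of the new coding exon
            off = _frame_offset_plus(gene, x)
            codon_pos = list(range(x + off, y - 2, 3))
            if codon_pos:
                for p in codon_pos:
                    _set(seq, p, _NON_STOP_CODONS[int(rng.integers(0, 61))])
                has_stop = bool(rng.random() < 0.5)
                if has_stop:
                    _set(seq, int(rng.choice(codon_pos)), "TAA")

        forms = [(x, y)] + ([alt] if alt else [])
        for fs, fe in forms:
            if gene.strand == "+":
                _set(seq, fs - 2, "AG")
                _set(seq, fe, "GT")
            else:
                _set(seq, fs - 2, "AC")
                _set(seq, fe, "CT")

        orient = (
            None if te.interval.strand == "."
            else ("sense" if te.interval.strand == gene.strand else "antisense")
        )
        for fs, fe in forms:
            if gene.strand == "+":
                donor_pos, acceptor_pos = fe - 1, fs
            else:
                donor_pos, acceptor_pos = fs, fe - 1
            truth.events.append(
                TruthEvent(
                    chrom=config.chrom, start=fs, end=fe, strand=gene.strand,
                    pattern=pattern, te_id=te.te_id,
                    donor_pos=donor_pos, acceptor_pos=acceptor_pos,
                    orientation=orient, host_gene=gene.gene_id,
                    placement="CDS" if in_cds else "UTR",
                    has_stop_in_frame=has_stop if (fs, fe) == (x, y) else None,
                )
            )
        planted.append(_PlantedEvent(gi, ii, pattern, (x, y), alt))
        truth.labels[te.te_id] = "exonized"

    # ----- TE insertions into first/last exons --------------------------
    for gi, gene in enumerate(genes):
        if rng.random() >= config.p_first_last_te:
            continue
        side = "first" if rng.random() < 0.5 else "last"
        exon = gene.first_exon() if side == "first" else gene.last_exon()
        if exon.length() < 46:
            continue
        tl = int(rng.integers(30, min(150, exon.length() - 8) + 1))
        start = int(rng.integers(exon.start + 2, exon.end - 2 - tl + 1))
        fam = str(rng.choice(TE_FAMILIES))
        clen = config.consensus_len[fam]
        cs = int(rng.integers(0, max(1, clen - tl + 1)))
        te_id = f"te{te_counter:05d}"
        te_counter += 1
        tes.append(
            TEAnnotation(
                te_id=te_id,
                interval=GenomeInterval(
                    config.chrom, start, start + tl,
                    "+" if rng.random() < 0.5 else "-",
                ),
                rep_name=f"{fam}_sim", rep_family=fam,
                consensus_start=cs, consensus_end=cs + tl,
            )
        )
        te_meta[te_id] = {"kind": "terminal", "gene_idx": gi, "intron_idx": None}
        truth.labels[te_id] = "exonic_terminal"

    # ----- in-frame TE insertions inside internal coding exons ----------
    n_cds_plants = config.n_internal_cds_te + config.n_internal_cds_te_disqualified
    if n_cds_plants:
        candidates = [
            (gi, k)
            for gi, gene in enumerate(genes)
            if gene.strand == "+"
            for k in range(1, len(gene.exons) - 1)
            if gene.exons[k].length() >= 60
            and gene.cds_start <= gene.exons[k].start
            and gene.exons[k].end <= gene.cds_end
        ]
        if len(candidates) < n_cds_plants:
            raise GenerationError(
                f"only {len(candidates)} internal CDS exons available for "
                f"{n_cds_plants} requested internal-CDS TE insertions"
            )
        order = rng.permutation(len(candidates))
        for j in range(n_cds_plants):
            qualifying = j < config.n_internal_cds_te
            gi, k = candidates[int(order[j])]
            gene = genes[gi]
            exon = gene.exons[k]
            max_codons = (exon.length() - 12) // 3
            # disqualified plants share the mod-3 length rule and are
            # rejected solely through a planted in-frame stop codon
            tl = 3 * int(rng.integers(4, min(40, max_codons) + 1))
            start = int(rng.integers(exon.start + 4, exon.end - 4 - tl + 1))
            off = _frame_offset_plus(gene, exon.start)
            codon_pos = [
                p for p in range(exon.start + off, exon.end - 2, 3)
                if p >= start and p + 3 <= start + tl
            ]
            for p in codon_pos:
                _set(seq, p, _NON_STOP_CODONS[int(rng.integers(0, 61))])
            if not qualifying:
                _set(seq, int(rng.choice(codon_pos)), "TAA")
            fam = "LINE"
            te_id = f"te{te_counter:05d}"
            te_counter += 1
            tes.append(
                TEAnnotation(
                    te_id=te_id,
                    interval=GenomeInterval(
                        config.chrom, start, start + tl,
                        "+" if rng.random() < 0.5 else "-",
                    ),
                    rep_name=f"{fam}_sim", rep_family=fam,
                    consensus_start=0, consensus_end=tl,
                )
            )
            te_meta[te_id] = {"kind": "internal_cds", "gene_idx": gi, "intron_idx": k}
            truth.labels[te_id] = "exonic_internal_nonspliced"
            truth.internal_cds.append((te_id, qualifying))

    # ----- remaining truth labels / orientation / refseq ----------------
    for te in tes:
        if te.te_id not in truth.labels:
            kind = te_meta[te.te_id]["kind"]
            truth.labels[te.te_id] = "intronic" if kind == "intronic" else "intergenic"
        meta = te_meta[te.te_id]
        gi = meta["gene_idx"]
        truth.in_refseq[te.te_id] = gi is not None
        if meta["kind"] == "intronic" or truth.labels[te.te_id] == "exonized":
            s = te.interval.strand
            truth.orientation[te.te_id] = (
                None if s == "." else ("sense" if s == genes[gi].strand else "antisense")
            )
        else:
            truth.orientation[te.te_id] = None

    # ----- EST sampling --------------------------------------------------
    by_gene_events: dict[int, list[_PlantedEvent]] = {}
    for ev in planted:
        by_gene_events.setdefault(ev.gene_idx, []).append(ev)

    alignments: list[SplicedAlignment] = []
    for gi, gene in enumerate(genes):
        gevents = by_gene_events.get(gi, [])
        for i in range(config.est_depth):
            blocks = [(e.start, e.end) for e in gene.exons]
            for ev in gevents:
                if i == 0:
                    choice = "A"
                elif i == 1:
                    choice = "skip" if ev.pattern == "cassette" else (
                        "B" if ev.alt else "A"
                    )
                else:
                    if ev.pattern == "cassette":
                        choice = "A" if rng.random() < 0.5 else "skip"
                    elif ev.alt:
                        choice = "A" if rng.random() < 0.5 else "B"
                    else:
                        choice = "A"
                if choice == "skip":
                    continue
                form = ev.primary if choice == "A" else ev.alt
                blocks.append(form)
            blocks.sort()
            if i >= 2 and rng.random() < config.p_truncate and len(blocks) > 2:
                # truncate at a uniform random 5' position
                span_lo, span_hi = blocks[0][0], blocks[-1][1]
                cut = int(rng.integers(span_lo + 1, span_hi - 1))
                if gene.strand == "+":
                    kept = [(max(s, cut), e) for s, e in blocks if e > cut]
                else:
                    kept = [(s, min(e, cut)) for s, e in blocks if s < cut]
                kept = [(s, e) for s, e in kept if e - s > 0]
                if len(kept) >= 2:
                    blocks = kept
            alignments.append(
                SplicedAlignment(
                    tx_id=f"est_{gene.gene_id}_{i}",
                    source="EST",
                    strand=gene.strand,
                    blocks=tuple(
                        GenomeInterval(config.chrom, s, e, gene.strand)
                        for s, e in blocks
                    ),
                )
            )

    # ----- per-intron and per-terminal-exon TE content -------------------
    te_ivs = [t.interval for t in tes]
    for gene in genes:
        for ii, intr in enumerate(gene.introns()):
            te_bp = union_overlap_bp(intr, te_ivs)
            truth.intron_records.append(
                {
                    "gene_id": gene.gene_id, "intron_index": ii,
                    "start": intr.start, "end": intr.end,
                    "length": intr.length(), "te_bp": te_bp,
                }
            )
        first, last = gene.first_exon(), gene.last_exon()
        truth.terminal_records[gene.gene_id] = {
            "first_len": first.length(),
            "first_te_bp": union_overlap_bp(first, te_ivs),
            "last_len": last.length(),
            "last_te_bp": union_overlap_bp(last, te_ivs),
            "single_exon": len(gene.exons) == 1,
        }

    genome = {config.chrom: bytes(seq).decode("ascii")}
    return SimResult(
        config=config, genome=genome, tes=tes, genes=genes,
        alignments=alignments, truth=truth,
    )


def write_sim(sim: SimResult, outdir) -> dict[str, Path]:
    """Write the generated genome, annotations, gene models, ESTs and
    truth record to *outdir*; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "rmsk_tab": outdir / "rmsk.tsv",
        "genepred": outdir / "genes.gp",
        "bed12": outdir / "ests.bed12",
        "truth": outdir / "truth.json",
    }
    fio.write_genome(sim.genome, paths["fasta"])
    fio.write_rmsk_tab(sim.tes, paths["rmsk_tab"])
    fio.write_genepred(sim.genes, paths["genepred"])
    fio.write_bed12(sim.alignments, paths["bed12"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataclasses.asdict(sim.truth), fh, indent=1, default=str)
    return paths
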