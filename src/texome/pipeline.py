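"""End-to-end convenience: classify TEs, detect and annotate
exonizations, and assemble the summary tables from loaded inputs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import ExonizationEvent, GeneModel, SplicedAlignment, TEAnnotation, TEContext
from .exonize import annotate_events, detect_exonizations
from .introns import intron_summary, intron_te_content
from .locate import classify_tes, orientation_bias_table
from .report import SpeciesSummary, pattern_tally, summarize
from .terminal import terminal_exon_stats


@dataclass
class PipelineResult:
    contexts: list[TEContext]
    events: list[ExonizationEvent]
    summary: SpeciesSummary
    pattern_counts: dict[str, int]
    orientation_table: pd.DataFrame
    intron_records: pd.DataFrame
    intron_stats: dict[str, float]
    terminal_stats: Optional[dict[str, float]]


def run_pipeline(
    tes: Sequence[TEAnnotation],
    alignments: Sequence[SplicedAlignment],
    genes: Sequence[GeneModel],
    genome: dict[str, str],
) -> PipelineResult:
    contexts = classify_tes(tes, alignments, genes, genome=genome)
    events = detect_exonizations(tes, alignments, genome)
    annotate_events(events, alignments, genes, genome)
    records = intron_te_content(genes, tes)
    try:
        term = terminal_exon_stats(genes, tes)
    except Exception:
        term = None
    return PipelineResult(
        contexts=contexts,
        events=events,
        summary=summarize(contexts, events, tes, genes),
        pattern_counts=pattern_tally(events),
        orientation_table=orientation_bias_table(contexts, tes, alignments),
        intron_records=records,
        intron_stats=intron_summary(records) if len(records) else {},
        terminal_stats=term,
    )


def contexts_frame(
    contexts: Sequence[TEContext], tes: Sequence[TEAnnotation]
) -> pd.DataFrame:
    fam = {te.te_id: te.rep_family for te in tes}
    strand = {te.te_id: te.interval.strand for te in tes}
    return pd.DataFrame(
        {
            "te_id": [c.te_id for c in contexts],
            "label": [c.label for c in contexts],
            "family": [fam[c.te_id] for c in contexts],
            "in_refseq": [c.in_refseq_gene for c in contexts],
            "strand": [strand[c.te_id] for c in contexts],
            "evidence_tx": [",".join(c.evidence_tx) for c in contexts],
        }
    )


def events_frame(events: Sequence[ExonizationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [e.exon.chrom for e in events],
            "start": [e.exon.start for e in events],
            "end": [e.exon.end for e in events],
            "strand": [e.exon.strand for e in events],
            "te_ids": [",".join(e.te_ids) for e in events],
            "pattern": [e.pattern for e in events],
            "orientation": [e.orientation or "undefined" for e in events],
            "placement": [e.gene_placement for e in events],
            "len_mod3": [e.len_mod3 for e in events],
            "donor_in_te": [e.donor_in_te for e in events],
            "acceptor_in_te": [e.acceptor_in_te for e in events],
            "donor_dinuc": [e.donor_dinuc for e in events],
            "acceptor_dinuc": [e.acceptor_dinuc for e in events],
            "n_support": [len(e.supporting_tx) for e in events],
        }
    )
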