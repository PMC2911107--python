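import numpy as np
import pytest

from texome.core import ExonizationEvent, GeneModel, GenomeInterval, SplicedAlignment, TEAnnotation, revcomp
from texome.exonize import (
    annotate_events,
    classify_splice_pattern,
    consensus_splice_profile,
    detect_exonizations,
    detect_internal_cds_insertions,
    frame_analysis,
    locate_in_gene,
)
from texome.simulate import SimConfig, generate


def _aln(blocks, strand="+", tx_id="t1", chrom="c"):
    return SplicedAlignment(
        tx_id, "EST", strand,
        tuple(GenomeInterval(chrom, s, e, strand) for s, e in blocks),
    )


def _te(start, end, strand="+", te_id="te1", fam="SINE", cons=None):
    cs, ce = cons if cons else (None, None)
    return TEAnnotation(te_id, GenomeInterval("c", start, end, strand), "x", fam, cs, ce)


def _genome_with(length, edits, chrom="c"):
    seq = list("A" * length)
    for pos, s in edits.items():
        seq[pos : pos + len(s)] = s
    return {chrom: "".join(seq)}


@pytest.fixture
def canonical_setup():
    # + strand transcript, internal block [120,150) flanked by GT..AG introns
    genome = _genome_with(
        400, {80: "GT", 118: "AG", 150: "GT", 198: "AG"}
    )
    aln = _aln([(50, 80), (120, 150), (200, 230)])
    return genome, aln


class TestDetection:
    def test_no_te_overlap_means_no_events(self, canonical_setup):
        genome, aln = canonical_setup
        assert detect_exonizations([_te(300, 350)], [aln], genome) == []

    def test_te_overlapping_internal_block_with_site_is_detected(self, canonical_setup):
        genome, aln = canonical_setup
        (ev,) = detect_exonizations([_te(110, 130)], [aln], genome)
        assert (ev.exon.start, ev.exon.end) == (120, 150)
        assert ev.acceptor_in_te and not ev.donor_in_te
        assert ev.donor_dinuc == "GT" and ev.acceptor_dinuc == "AG"

    def test_non_canonical_donor_rejected(self):
        genome = _genome_with(400, {80: "GT", 118: "AG", 150: "CC", 198: "AG"})
        aln = _aln([(50, 80), (120, 150), (200, 230)])
        assert detect_exonizations([_te(110, 130)], [aln], genome) == []

    def test_te_inside_block_without_boundary_rejected(self, canonical_setup):
        genome, aln = canonical_setup
        assert detect_exonizations([_te(125, 145)], [aln], genome) == []

    def test_terminal_blocks_never_yield_events(self, canonical_setup):
        genome, aln = canonical_setup
        assert detect_exonizations([_te(45, 60)], [aln], genome) == []

    def test_missing_chromosome_raises(self, canonical_setup):
        genome, aln = canonical_setup
        with pytest.raises(KeyError, match="c"):
            detect_exonizations([_te(110, 130)], [aln], {"other": "ACGT"})

    def test_duplicate_events_collapsed_with_union_support(self, canonical_setup):
        genome, aln = canonical_setup
        aln2 = _aln([(40, 80), (120, 150), (200, 240)], tx_id="t2")
        (ev,) = detect_exonizations([_te(110, 130)], [aln, aln2], genome)
        assert ev.supporting_tx == ["t1", "t2"]

    def test_detection_independent_of_input_order(self, sim_default):
        sim = sim_default
        fwd = detect_exonizations(sim.tes, sim.alignments, sim.genome)
        rng = np.random.default_rng(5)
        alns = list(sim.alignments)
        tes = list(sim.tes)
        rng.shuffle(alns)
        rng.shuffle(tes)
        rev = detect_exonizations(tes, alns, sim.genome)
        assert [e.key for e in fwd] == [e.key for e in rev]
        assert [e.te_ids for e in fwd] == [e.te_ids for e in rev]

    def test_planted_events_recovered_exactly(self):
        sim = generate(SimConfig(seed=19, n_genes=25, p_exonization=0.3, est_depth=10))
        events = detect_exonizations(sim.tes, sim.alignments, sim.genome)
        assert {e.key for e in events} == {e.key for e in sim.truth.events}
        assert len(sim.truth.events) >= 10

    def test_detected_dinucleotides_reextract_as_canonical(self, sim_default):
        seq = sim_default.genome[sim_default.config.chrom]
        events = detect_exonizations(sim_default.tes, sim_default.alignments, sim_default.genome)
        for ev in events:
            left = seq[ev.exon.start - 2 : ev.exon.start]
            right = seq[ev.exon.end : ev.exon.end + 2]
            if ev.exon.strand == "+":
                assert (right[:2], left) == ("GT", "AG")
            else:
                assert (revcomp(left), revcomp(right)) == ("GT", "AG")


class TestSplicePattern:
    def _event(self, start, end, strand="+"):
        return ExonizationEvent(
            exon=GenomeInterval("c", start, end, strand),
            te_ids=["te1"], donor_pos=end - 1, acceptor_pos=start,
            donor_in_te=True, acceptor_in_te=False,
            donor_dinuc="GT", acceptor_dinuc="AG", orientation="sense",
        )

    def test_all_spanning_include_identically_is_constitutive(self):
        alns = [
            _aln([(0, 100), (200, 250), (400, 500)], tx_id=f"t{i}") for i in range(3)
        ]
        assert classify_splice_pattern(self._event(200, 250), alns) == "constitutive"

    def test_single_spanning_alignment_is_unclassified(self):
        alns = [_aln([(0, 100), (200, 250), (400, 500)])]
        assert classify_splice_pattern(self._event(200, 250), alns) == "unclassified"

    def test_skipping_alignment_makes_cassette(self):
        alns = [
            _aln([(0, 100), (200, 250), (400, 500)], tx_id="inc"),
            _aln([(0, 100), (400, 500)], tx_id="skp"),
        ]
        assert classify_splice_pattern(self._event(200, 250), alns) == "cassette"

    def test_shifted_donor_is_alt5_on_plus_strand(self):
        alns = [
            _aln([(0, 100), (200, 250), (400, 500)], tx_id="a"),
            _aln([(0, 100), (200, 262), (400, 500)], tx_id="b"),
        ]
        assert classify_splice_pattern(self._event(200, 250), alns) == "alt5"

    def test_shifted_donor_is_alt5_on_minus_strand(self):
        # minus strand: the donor is the genomic-left exon edge
        alns = [
            _aln([(0, 100), (200, 250), (400, 500)], strand="-", tx_id="a"),
            _aln([(0, 100), (191, 250), (400, 500)], strand="-", tx_id="b"),
        ]
        assert classify_splice_pattern(self._event(200, 250, "-"), alns) == "alt5"

    def test_shifted_acceptor_is_alt3_on_plus_strand(self):
        alns = [
            _aln([(0, 100), (200, 250), (400, 500)], tx_id="a"),
            _aln([(0, 100), (191, 250), (400, 500)], tx_id="b"),
        ]
        assert classify_splice_pattern(self._event(200, 250), alns) == "alt3"

    def test_cassette_beats_alternative_site_evidence(self):
        alns = [
            _aln([(0, 100), (200, 250), (400, 500)], tx_id="a"),
            _aln([(0, 100), (200, 262), (400, 500)], tx_id="b"),
            _aln([(0, 100), (400, 500)], tx_id="c"),
        ]
        assert classify_splice_pattern(self._event(200, 250), alns) == "cassette"

    def test_planted_patterns_recovered(self):
        sim = generate(
            SimConfig(seed=23, n_genes=40, p_exonization=0.35, est_depth=10)
        )
        events = detect_exonizations(sim.tes, sim.alignments, sim.genome)
        truth = {e.key: e.pattern for e in sim.truth.events}
        assert len(events) >= 20
        correct = sum(
            classify_splice_pattern(ev, sim.alignments) == truth[ev.key]
            for ev in events
        )
        assert correct / len(events) >= 0.95


def _coding_gene(exons, cds, strand="+", gene_id="g1"):
    return GeneModel(
        gene_id, gene_id + "t", strand,
        tuple(GenomeInterval("c", s, e, strand) for s, e in exons),
        cds[0], cds[1],
    )


class TestGenePlacementAndFrame:
    def _event(self, start, end, strand="+"):
        return ExonizationEvent(
            exon=GenomeInterval("c", start, end, strand),
            te_ids=["te1"], donor_pos=end - 1, acceptor_pos=start,
            donor_in_te=True, acceptor_in_te=False,
            donor_dinuc="GT", acceptor_dinuc="AG", orientation="sense",
        )

    def test_event_in_coding_span_is_cds(self):
        gene = _coding_gene([(0, 100), (500, 600)], (50, 550))
        assert locate_in_gene(self._event(200, 273), [gene]) == "CDS"

    def test_event_in_utr_intron_is_utr(self):
        # CDS confined to the second exon; the first intron is 5' UTR
        gene = _coding_gene([(0, 100), (500, 600)], (510, 550))
        assert locate_in_gene(self._event(200, 273), [gene]) == "UTR"

    def test_opposite_strand_gene_does_not_annotate(self):
        gene = _coding_gene([(0, 100), (500, 600)], (50, 550), strand="-")
        assert locate_in_gene(self._event(200, 273), [gene]) == "unannotated"

    def test_length_73_disrupts_frame(self):
        gene = _coding_gene([(0, 100), (500, 600)], (50, 550))
        genome = _genome_with(700, {})
        mod3, _ = frame_analysis(self._event(200, 273), [gene], genome)
        assert mod3 == 1

    def test_stop_free_length_81_preserves_frame(self):
        gene = _coding_gene([(0, 99), (500, 600)], (0, 550))
        genome = _genome_with(700, {})  # poly-A: no stop codons anywhere
        mod3, has_stop = frame_analysis(self._event(200, 281), [gene], genome)
        assert (mod3, has_stop) == (0, False)

    def test_engineered_in_frame_taa_detected_on_minus_strand(self):
        # upstream coding length 55 -> codons resume at exon offset 2
        gene = _coding_gene([(0, 30), (60, 90), (120, 150)], (5, 145), strand="-")
        eseq = "CCTAACCCCCCC"
        genome = _genome_with(200, {40: revcomp(eseq)})
        mod3, has_stop = frame_analysis(self._event(40, 52, "-"), [gene], genome)
        assert (mod3, has_stop) == (0, True)

    def test_planted_stop_truth_recovered(self, sim_default):
        sim = sim_default
        events = detect_exonizations(sim.tes, sim.alignments, sim.genome)
        annotate_events(events, sim.alignments, sim.genes, sim.genome)
        truth = {e.key: e.has_stop_in_frame for e in sim.truth.events}
        checked = 0
        for ev in events:
            expect = truth.get(ev.key)
            if expect is None:
                continue
            assert ev.gene_placement == "CDS"
            assert ev.has_stop_in_frame == expect
            checked += 1
        assert checked >= 3


class TestInternalCDSInsertions:
    def test_non_mod3_te_excluded(self):
        gene = _coding_gene([(0, 50), (132, 800), (868, 920)], (10, 910))
        genome = _genome_with(1000, {})
        te = _te(200, 300, te_id="teX")  # length 100, not divisible by 3
        assert detect_internal_cds_insertions([te], [gene], genome) == []

    def test_in_frame_stop_free_te_reported_with_flank_lengths(self):
        # internal exon of 668 bp flanked by 82 and 68 bp introns
        gene = _coding_gene([(0, 50), (132, 800), (868, 920)], (10, 910))
        genome = _genome_with(1000, {})
        te = _te(200, 500, te_id="teX")  # 300 bp, mod 3 == 0, poly-A: stop-free
        (ins,) = detect_internal_cds_insertions([te], [gene], genome)
        assert ins.exon.length() == 668
        assert (ins.upstream_intron_len, ins.downstream_intron_len) == (82, 68)
        assert ins.te_len == 300

    def test_in_frame_stop_disqualifies(self):
        gene = _coding_gene([(0, 50), (132, 800), (868, 920)], (10, 910))
        # frame offset in exon: cum CDS before = 40 -> codons start at 132+2
        genome = _genome_with(1000, {302: "TAA"})
        te = _te(200, 500, te_id="teX")
        assert detect_internal_cds_insertions([te], [gene], genome) == []

    def test_planted_qualifying_set_recovered_exactly(self):
        sim = generate(
            SimConfig(
                seed=29, n_genes=30, p_exonization=0.0,
                n_internal_cds_te=20, n_internal_cds_te_disqualified=20,
            )
        )
        found = {i.te_id for i in detect_internal_cds_insertions(sim.tes, sim.genes, sim.genome)}
        qualifying = {t for t, q in sim.truth.internal_cds if q}
        assert found == qualifying
        assert len(qualifying) == 20


class TestConsensusProfile:
    def _event(self, start, end, donor_te, acceptor_te=None, strand="+", orient="sense"):
        return ExonizationEvent(
            exon=GenomeInterval("c", start, end, strand),
            te_ids=[donor_te],
            donor_pos=end - 1 if strand == "+" else start,
            acceptor_pos=start if strand == "+" else end - 1,
            donor_in_te=True, acceptor_in_te=acceptor_te is not None,
            donor_dinuc="GT", acceptor_dinuc="AG", orientation=orient,
            donor_te_id=donor_te, acceptor_te_id=acceptor_te,
        )

    def test_identity_mapping_for_sense_te(self):
        # TE aligned 1:1 to consensus positions [10, 110)
        te = _te(1000, 1100, cons=(10, 110), te_id="teC")
        ev = self._event(1000, 1050, "teC", "teC")
        prof = consensus_splice_profile([ev], [te])
        donor = prof[prof["site"] == "donor"]
        acceptor = prof[prof["site"] == "acceptor"]
        assert donor["consensus_pos"].tolist() == [10 + 49]
        assert acceptor["consensus_pos"].tolist() == [10]

    def test_antisense_te_reverses_mapping(self):
        te = _te(1000, 1100, strand="-", cons=(10, 110), te_id="teC")
        ev = self._event(1000, 1050, "teC", "teC", orient="antisense")
        prof = consensus_splice_profile([ev], [te])
        # genomic TE end maps to consensus_start for minus-strand TEs
        acceptor = prof[prof["site"] == "acceptor"]
        assert acceptor["consensus_pos"].tolist() == [10 + 99]

    def test_site_outside_te_goes_to_sentinel_bin(self):
        te = _te(1000, 1100, cons=(10, 110), te_id="teC")
        ev = self._event(950, 1050, "teC", None)
        prof = consensus_splice_profile([ev], [te])
        acceptor = prof[prof["site"] == "acceptor"]
        assert acceptor["consensus_pos"].tolist() == [-1]

    def test_te_without_consensus_is_skipped(self):
        te = _te(1000, 1100, te_id="teC")
        ev = self._event(1000, 1050, "teC", "teC")
        assert len(consensus_splice_profile([ev], [te])) == 0

    def test_planted_offsets_recovered_exactly(self, sim_default):
        sim = sim_default
        by_id = {t.te_id: t for t in sim.tes}
        events = detect_exonizations(sim.tes, sim.alignments, sim.genome)
        prof = consensus_splice_profile(events, sim.tes)
        # recompute expected donor consensus position for each event whose
        # donor lies in a 1:1-aligned TE
        expected = []
        for ev in events:
            te = by_id.get(ev.donor_te_id)
            if te is None or te.consensus_start is None:
                continue
            iv = te.interval
            if iv.strand == "-":
                expected.append(te.consensus_start + (iv.end - 1 - ev.donor_pos))
            else:
                expected.append(te.consensus_start + (ev.donor_pos - iv.start))
        got = prof[prof["site"] == "donor"]
        assert sorted(
            p for p, n in zip(got["consensus_pos"], got["count"]) for _ in range(n)
        ) == sorted(expected)
        assert len(expected) > 0
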