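import numpy as np
import pytest

from texome.core import GenomeInterval, SplicedAlignment, TEAnnotation
from texome.locate import classify_te, classify_tes, orientation, orientation_bias_table
from texome.simulate import SimConfig, generate
from texome.stats import chi2_goodness_of_fit
from _oracles import oracle_context_label, oracle_in_refseq


def te(start, end, strand="+", fam="SINE", te_id="te1"):
    return TEAnnotation(te_id, GenomeInterval("c", start, end, strand), "x", fam)


def aln(blocks, strand="+", tx_id="t1"):
    return SplicedAlignment(
        tx_id, "EST", strand,
        tuple(GenomeInterval("c", s, e, strand) for s, e in blocks),
    )


class TestClassification:
    def test_no_overlap_is_intergenic(self):
        ctx = classify_te(te(1000, 1100), [aln([(0, 100), (200, 300)])], [])
        assert ctx.label == "intergenic"
        assert not ctx.in_refseq_gene

    def test_te_inside_est_gap_is_intronic(self):
        ctx = classify_te(te(120, 180), [aln([(0, 100), (200, 300)])], [])
        assert ctx.label == "intronic"
        assert ctx.evidence_tx == ["t1"]

    def test_te_over_internal_block_boundary_is_exonized(self):
        a = aln([(0, 100), (200, 300), (400, 500)])
        ctx = classify_te(te(150, 250), [a], [])
        assert ctx.label == "exonized"

    def test_te_inside_internal_block_without_site_is_nonspliced(self):
        a = aln([(0, 100), (200, 300), (400, 500)])
        ctx = classify_te(te(220, 280), [a], [])
        assert ctx.label == "exonic_internal_nonspliced"

    def test_te_over_terminal_block_only_is_terminal(self):
        a = aln([(0, 100), (200, 300)])
        ctx = classify_te(te(10, 60), [a], [])
        assert ctx.label == "exonic_terminal"

    def test_partition_covers_all_tes(self, sim_default):
        contexts = classify_tes(
            sim_default.tes, sim_default.alignments, sim_default.genes
        )
        assert len(contexts) == len(sim_default.tes)
        assert all(c.label != "ambiguous" for c in contexts)

    def test_labels_match_per_base_oracle(self):
        sim = generate(SimConfig(seed=21, n_genes=15, p_exonization=0.15, p_first_last_te=0.3))
        contexts = classify_tes(sim.tes, sim.alignments, sim.genes)
        for t, c in zip(sim.tes, contexts):
            assert c.label == oracle_context_label(t, sim.alignments)
            assert c.in_refseq_gene == oracle_in_refseq(t, sim.genes)

    def test_adding_alignments_never_moves_toward_intergenic(self, sim_default):
        rank = {
            "intergenic": 0, "intronic": 1,
            "exonic_terminal": 2, "exonic_internal_nonspliced": 2, "exonized": 3,
            "ambiguous": 0,
        }
        half = sim_default.alignments[: len(sim_default.alignments) // 2]
        partial = classify_tes(sim_default.tes, half, sim_default.genes)
        full = classify_tes(sim_default.tes, sim_default.alignments, sim_default.genes)
        for p, f in zip(partial, full):
            assert rank[f.label] >= rank[p.label]


class TestOrientation:
    def test_equal_strands_are_sense(self):
        assert orientation(te(0, 10, "+"), "+") == "sense"

    def test_opposite_strands_are_antisense(self):
        assert orientation(te(0, 10, "-"), "+") == "antisense"

    def test_unstranded_te_is_undefined(self):
        with pytest.raises(ValueError):
            orientation(te(0, 10, "."), "+")

    def test_strand_flip_swaps_tallies_exactly(self, sim_default):
        contexts = classify_tes(sim_default.tes, sim_default.alignments, sim_default.genes)
        table = orientation_bias_table(contexts, sim_default.tes, sim_default.alignments)
        flipped_tes = [
            TEAnnotation(
                t.te_id,
                GenomeInterval(
                    t.interval.chrom, t.interval.start, t.interval.end,
                    {"+": "-", "-": "+", ".": "."}[t.interval.strand],
                ),
                t.rep_name, t.rep_family, t.consensus_start, t.consensus_end,
            )
            for t in sim_default.tes
        ]
        flipped = orientation_bias_table(contexts, flipped_tes, sim_default.alignments)
        assert (table["sense"] == flipped["antisense"]).all()
        assert (table["antisense"] == flipped["sense"]).all()
        assert table.to_numpy().sum() > 0

    def test_all_unstranded_gives_zero_table(self):
        sim = generate(SimConfig(seed=9, n_genes=6, p_unstranded=1.0))
        contexts = classify_tes(sim.tes, sim.alignments, sim.genes)
        table = orientation_bias_table(contexts, sim.tes, sim.alignments)
        assert table.to_numpy().sum() == 0

    def test_planted_bias_recovered_in_table(self):
        sim = generate(
            SimConfig(
                seed=13, n_genes=60, p_exonization=0.0,
                p_antisense_per_family={f: 0.9 for f in ("SINE", "LINE", "LTR", "DNA")},
            )
        )
        contexts = classify_tes(sim.tes, sim.alignments, sim.genes)
        table = orientation_bias_table(contexts, sim.tes, sim.alignments)
        total = table.to_numpy().sum()
        anti = table["antisense"].sum()
        assert anti / total > 0.8


class TestGoodnessOfFitBehaviour:
    """Operating characteristics of the 50:50 orientation test."""

    def test_type_i_error_is_controlled_under_the_null(self):
        rng = np.random.default_rng(31)
        low_p = 0
        for _ in range(100):
            k = rng.binomial(500, 0.5)
            res = chi2_goodness_of_fit([k, 500 - k], [0.5, 0.5])
            if res.p_value <= 0.001:
                low_p += 1
        assert low_p <= 1  # p > 0.001 in >= 99% of null replicates

    def test_strong_bias_is_detected(self):
        rng = np.random.default_rng(37)
        detected = 0
        for _ in range(100):
            k = rng.binomial(200, 0.9)
            res = chi2_goodness_of_fit([k, 200 - k], [0.5, 0.5])
            if res.p_value < 0.01:
                detected += 1
        assert detected >= 99
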