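"""The identification cascade: filters, strand rule, merge, expression gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retlnc import identify
from retlnc.identify import (
    assign_strand,
    expression_gate,
    filter_long_read_set,
    filter_short_read_set,
    merge_sources,
)
from retlnc.models import ValidationError

from conftest import make_locus, make_matrix, make_transcript
from oracles import binomial_strand_p


CODING = [
    make_transcript(
        "pc.t1", "pc", exons=((1000, 1300), (3000, 3300), (5000, 5400)),
        strand="+", source="annotation", biotype="coding",
    )
]


class TestShortReadFilter:
    def run(self, transcripts, **kw):
        cp = {t.transcript_id: kw.pop("label", "noncoding") for t in transcripts}
        return filter_short_read_set(transcripts, CODING, cp, **kw)

    def test_short_transcript_removed(self):
        t = make_transcript("t", "g", exons=((10000, 10080), (10200, 10270)))  # 150 nt
        assert self.run([t]) == []

    def test_single_exon_removed_even_if_long(self):
        t = make_transcript("t", "g", exons=((10000, 10500),))
        assert self.run([t]) == []

    def test_one_base_exonic_overlap_removed(self):
        # second coding exon is [3000, 3300); lnc exon ending at 3001 overlaps 1 base
        hit = make_transcript("t", "g", exons=((2800, 3001), (4000, 4200)))
        assert self.run([hit]) == []
        moved = make_transcript("t", "g", exons=((2800, 3000), (4000, 4200)))
        assert [t.transcript_id for t in self.run([moved])] == ["t"]

    def test_opposite_strand_exon_overlap_also_removed(self):
        hit = make_transcript("t", "g", exons=((2800, 3001), (4000, 4200)), strand="-")
        assert self.run([hit]) == []

    def test_coding_potential_label_gates(self):
        t = make_transcript("t", "g", exons=((10000, 10200), (10400, 10600)))
        assert filter_short_read_set([t], CODING, {"t": "coding"}) == []
        assert len(filter_short_read_set([t], CODING, {"t": "noncoding"})) == 1
        with pytest.warns(UserWarning):
            assert filter_short_read_set([t], CODING, {}) == []
        with pytest.raises(ValidationError):
            filter_short_read_set([t], CODING, {}, on_missing_potential="error")

    def test_agrees_with_per_base_oracle_on_random_layouts(self):
        rng = np.random.default_rng(42)
        coding_exons = [(s, e) for t in CODING for (s, e) in
                        [(ex.start, ex.end) for ex in t.exons]]
        base = np.zeros(20000, dtype=bool)
        for s, e in coding_exons:
            base[s:e] = True
        for _ in range(200):
            s1 = int(rng.integers(0, 12000))
            l1 = int(rng.integers(100, 400))
            gap = int(rng.integers(50, 500))
            l2 = int(rng.integers(100, 400))
            t = make_transcript("t", "g", exons=((s1, s1 + l1), (s1 + l1 + gap, s1 + l1 + gap + l2)))
            mask = np.zeros(20000, dtype=bool)
            for e_ in t.exons:
                mask[e_.start: e_.end] = True
            overlap = bool((mask & base).any())
            kept = bool(self.run([t])) if t.exonic_length >= 200 else False
            expected = (not overlap) and t.exonic_length >= 200
            assert kept == expected


class TestAssignStrand:
    def test_clear_majority_assigned(self):
        call = assign_strand(100, 10)
        assert call.assigned_strand == "+"
        assert call.fold == pytest.approx(10.0)
        assert call.chi2 == pytest.approx(73.636363, abs=1e-5)
        assert call.p_value < 1e-15

    def test_fold_rule_blocks_weak_majorities(self):
        call = assign_strand(30, 20)  # fold 1.5 <= 2 regardless of p
        assert call.assigned_strand == "unassigned"

    def test_mirror_symmetry(self):
        call = assign_strand(10, 100)
        ref = assign_strand(100, 10)
        assert call.assigned_strand == "-"
        assert call.p_value == ref.p_value and call.fold == ref.fold

    def test_no_reads_unassigned_with_p_one(self):
        call = assign_strand(0, 0)
        assert call.assigned_strand == "unassigned" and call.p_value == 1.0

    def test_decision_matches_exact_binomial_oracle(self):
        # chi-square approximation and exact binomial should agree at
        # alpha=0.05 whenever counts are not tiny
        for plus in range(0, 120, 7):
            for minus in range(0, 120, 7):
                if plus + minus < 20:
                    continue
                call = assign_strand(plus, minus)
                exact = binomial_strand_p(plus, minus)
                if abs(call.p_value - 0.05) > 0.02:  # away from the boundary
                    assert (call.p_value <= 0.05) == (exact <= 0.05), (plus, minus)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_swap_equivariance(self, plus, minus):
        a = assign_strand(plus, minus)
        b = assign_strand(minus, plus)
        assert a.p_value == b.p_value and a.fold == b.fold
        flip = {"+": "-", "-": "+", "unassigned": "unassigned"}
        assert b.assigned_strand == flip[a.assigned_strand]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            assign_strand(-1, 5)


class TestLongReadFilter:
    def test_shared_intron_same_strand_removed(self):
        # coding introns: (1300, 3000) and (3300, 5000) on "+"
        t = make_transcript("t", "g", exons=((1200, 1300), (3000, 3100)), strand="+",
                            source="long_read")
        assert filter_long_read_set([t], {}, CODING) == []

    def test_identical_intron_opposite_strand_kept(self):
        t = make_transcript("t", "g", exons=((1200, 1300), (3000, 3100)), strand="-",
                            source="long_read")
        assert len(filter_long_read_set([t], {}, CODING)) == 1

    def test_unassigned_strand_removed(self):
        t = make_transcript("t", "g", exons=((8000, 8200), (8400, 8600)), strand=".",
                            source="long_read")
        call = assign_strand(10, 10, "t")
        assert filter_long_read_set([t], {"t": call}, CODING) == []
        good = assign_strand(100, 5, "t")
        (kept,) = filter_long_read_set([t], {"t": good}, CODING)
        assert kept.strand == "+"

    def test_missing_strand_call_is_an_error(self):
        t = make_transcript("t", "g", exons=((8000, 8200), (8400, 8600)), strand=".",
                            source="long_read")
        with pytest.raises(ValidationError):
            filter_long_read_set([t], {}, CODING)


class TestMergeSources:
    def test_identical_intron_chain_collapses_across_sources(self):
        sr = make_transcript("sr1", "g", exons=((100, 300), (500, 800)), source="short_read")
        lr = make_transcript("lr1", "g", exons=((80, 300), (500, 900)), source="long_read")
        loci, report = merge_sources([], [sr], [lr])
        assert report.n_transcripts == 1 and report.n_loci == 1
        (t,) = loci[0].transcripts
        assert t.source_set == {"short_read", "long_read"}
        assert (t.span.start, t.span.end) == (80, 900)  # widest terminal exons

    def test_one_bp_overlap_same_strand_clusters(self):
        a = make_transcript("a", "ga", exons=((100, 200), (400, 500)))
        b = make_transcript("b", "gb", exons=((499, 600), (700, 800)))
        loci, _ = merge_sources([], [a], [b])
        assert len(loci) == 1
        opposite = make_transcript("b", "gb", exons=((499, 600), (700, 800)), strand="-")
        loci2, _ = merge_sources([], [a], [opposite])
        assert len(loci2) == 2

    def test_transitive_chain_clusters_into_one_locus(self):
        a = make_transcript("a", "ga", exons=((100, 300), (350, 500)))
        b = make_transcript("b", "gb", exons=((450, 600), (650, 900)))
        c = make_transcript("c", "gc", exons=((850, 1000), (1100, 1300)))
        # a-b overlap, b-c overlap, a-c disjoint
        loci, _ = merge_sources([], [a, b], [c])
        assert len(loci) == 1 and len(loci[0].transcripts) == 3

    def test_single_exon_transcripts_merge_by_span_overlap(self):
        a = make_transcript("a", "ga", exons=((100, 500),), source="annotation")
        b = make_transcript("b", "gb", exons=((400, 900),), source="annotation")
        c = make_transcript("c", "gc", exons=((2000, 2400),), source="annotation")
        loci, report = merge_sources([a, b, c], [], [])
        assert report.n_transcripts == 2
        spans = sorted((l.span.start, l.span.end) for l in loci)
        assert spans == [(100, 900), (2000, 2400)]

    def test_unstranded_transcript_rejected(self):
        t = make_transcript("t", "g", strand=".", source="long_read")
        with pytest.raises(ValidationError):
            merge_sources([], [], [t])

    def test_idempotent_and_order_invariant(self, toy_genome):
        truth = toy_genome.truth
        stranded = [t.with_strand(truth.unknown_strand[t.transcript_id])
                    if t.strand == "." else t for t in toy_genome.lr_set]
        sr = filter_short_read_set(
            toy_genome.sr_set, toy_genome.coding_transcripts, toy_genome.coding_potential
        )
        lr = filter_long_read_set(stranded, {}, toy_genome.coding_transcripts)
        loci, report = merge_sources(toy_genome.annotation_set, sr, lr)

        def structures(loci_):
            return sorted(
                sorted((t.intron_chain, t.span.start, t.span.end, t.source_set)
                       for t in l.transcripts)
                for l in loci_
            )

        merged_pool = [t for l in loci for t in l.transcripts]
        again, report2 = merge_sources(merged_pool, [], [])
        assert structures(again) == structures(loci)
        assert report2.n_loci == report.n_loci
        assert report2.n_transcripts == report.n_transcripts

        swapped, report3 = merge_sources(toy_genome.annotation_set, lr, sr)
        assert structures(swapped) == structures(loci)
        assert report3.gene_combo_counts == report.gene_combo_counts

    def test_accounting_matches_planted_truth(self, toy_genome):
        truth = toy_genome.truth
        stranded = [t.with_strand(truth.unknown_strand[t.transcript_id])
                    if t.strand == "." else t for t in toy_genome.lr_set]
        sr = filter_short_read_set(
            toy_genome.sr_set, toy_genome.coding_transcripts, toy_genome.coding_potential
        )
        lr = filter_long_read_set(stranded, {}, toy_genome.coding_transcripts)
        _, report = merge_sources(toy_genome.annotation_set, sr, lr)
        report.validate()  # inclusion-exclusion internal consistency
        assert report.n_loci == truth.expected_locus_count
        assert report.n_transcripts == truth.expected_transcript_count
        assert dict(report.gene_combo_counts) == truth.expected_gene_combos
        assert dict(report.transcript_combo_counts) == truth.expected_transcript_combos
        assert dict(report.novel_isoforms_by_source) == truth.expected_novel_isoforms


class TestExpressionGate:
    def make(self, values):
        return make_matrix(values, columns=["a_r1", "a_r2"], conditions=["a", "a"],
                           index=["L1"])

    def test_gate_boundaries(self):
        locus = make_locus("L1")
        assert expression_gate([locus], self.make([[0.99, 0.5]])) == []
        assert len(expression_gate([locus], self.make([[1.0, 0.0]]))) == 1
        assert expression_gate([locus], self.make([[0.0, 0.0]])) == []

    def test_stage_replicate_mode(self):
        locus = make_locus("L1")
        em = self.make([[1.5, 0.8]])
        assert expression_gate([locus], em, mode="stage_replicates") == []
        em2 = self.make([[1.5, 1.2]])
        assert len(expression_gate([locus], em2, mode="stage_replicates")) == 1

    def test_missing_locus_is_an_error(self):
        other = make_locus("L2")
        with pytest.raises(ValidationError):
            expression_gate([other], self.make([[2.0, 2.0]]))
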