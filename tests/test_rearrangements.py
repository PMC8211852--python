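"""Translocation blocks, breakpoint refinement, reassembly and neo-loops."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoloopscan.matrix import bin_contacts
from neoloopscan.rearrangements import (
    CandidateBlock,
    CoordinateTransform,
    Fragment,
    TranslocationEvent,
    annotate_event,
    detect_interchrom_blocks,
    detect_neo_loops,
    junction_continuity,
    reassemble_matrix,
    refine_breakpoints,
)
from neoloopscan.simulate import (
    ChimericRead,
    RearrangementSpec,
    StructureSpec,
    plant_rearrangement,
    simulate_contact_map,
)

BP_A, BP_B = 6_123_457, 4_987_655


def simulate_event(sv_genome, seed=7, frac=1.0, n_reads=6, neo=None, fa="left", fb="right"):
    ev = RearrangementSpec("translocation", "chr1", BP_A, "chr2", BP_B,
                           flank_a=fa, flank_b=fb, clonal_fraction=frac,
                           n_chimeric_reads=n_reads, n_decoy_reads=10,
                           neo_loops=neo or [])
    recs = simulate_contact_map(sv_genome, StructureSpec(), 1_000_000, seed=seed)
    recs, reads = plant_rearrangement(recs, sv_genome, ev, seed=seed + 1000)
    return bin_contacts(recs, sv_genome, 40_000), reads, ev


class TestBlockDetection:
    def test_no_event_no_candidates(self, sv_genome, sv_controls):
        recs = simulate_contact_map(sv_genome, StructureSpec(), 1_000_000, seed=55)
        cm = bin_contacts(recs, sv_genome, 40_000)
        assert detect_interchrom_blocks(cm, sv_controls) == []

    def test_planted_event_yields_block_containing_breakpoints(self, sv_genome, sv_controls):
        cm, _, _ = simulate_event(sv_genome)
        cands = detect_interchrom_blocks(cm, sv_controls)
        assert len(cands) == 1
        c = cands[0]
        assert c.a_start <= BP_A - 1 < c.a_end
        assert c.b_start <= BP_B - 1 < c.b_end

    def test_block_also_in_all_controls_is_filtered(self, sv_genome):
        cm, reads, ev = simulate_event(sv_genome)
        ctrl_with_event = []
        for s in (70, 71):
            recs = simulate_contact_map(sv_genome, StructureSpec(), 1_000_000, seed=s)
            recs, _ = plant_rearrangement(recs, sv_genome, ev, seed=s + 10)
            ctrl_with_event.append(bin_contacts(recs, sv_genome, 40_000))
        cands = detect_interchrom_blocks(cm, ctrl_with_event)
        assert all(c.control_present for c in cands)
        events = refine_breakpoints(cands, reads, cm.genome)
        assert events == []  # control-present candidates are dropped


class TestRefinement:
    def make_candidate(self):
        return CandidateBlock("chr1", 5_000_000, 7_000_000, "chr2", 4_000_000, 6_000_000,
                              enrichment=10.0, p=1e-9, q=1e-9)

    def reads_at(self, n, linker=False, pos=(BP_A, BP_B), strands=("+", "+")):
        return [ChimericRead(f"r{i}", "chr1", pos[0], strands[0],
                             "chr2", pos[1], strands[1], linker) for i in range(n)]

    def test_five_reads_refine_to_exact_coordinates(self, sv_genome):
        events = refine_breakpoints([self.make_candidate()], self.reads_at(5), sv_genome)
        e = events[0]
        assert e.refined and (e.bp_a, e.bp_b) == (BP_A, BP_B)
        assert (e.flank_a, e.flank_b) == ("left", "right")
        assert e.support == 5

    def test_exactly_three_reads_do_not_refine(self, sv_genome):
        events = refine_breakpoints([self.make_candidate()], self.reads_at(3), sv_genome)
        assert not events[0].refined
        assert events[0].support == 3

    def test_linker_reads_are_discarded(self, sv_genome):
        events = refine_breakpoints([self.make_candidate()],
                                    self.reads_at(5, linker=True), sv_genome)
        assert not events[0].refined

    def test_strand_tie_leaves_candidate_unrefined(self, sv_genome):
        reads = self.reads_at(2, strands=("+", "+")) + self.reads_at(2, strands=("-", "-"))
        events = refine_breakpoints([self.make_candidate()], reads, sv_genome, min_support=3)
        assert not events[0].refined

    def test_minus_strands_give_right_and_left_flanks(self, sv_genome):
        events = refine_breakpoints([self.make_candidate()],
                                    self.reads_at(5, strands=("-", "-")), sv_genome)
        assert (events[0].flank_a, events[0].flank_b) == ("right", "left")

    def test_unknown_chromosome_rejected(self, sv_genome):
        bad = [ChimericRead("r", "chrX", 1, "+", "chr2", 1, "+", False)]
        with pytest.raises(ValueError, match="unknown chromosome"):
            refine_breakpoints([self.make_candidate()], bad, sv_genome)


class TestReassembly:
    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10**6 - 1), st.booleans(), st.booleans())
    def test_transform_round_trip_is_identity(self, offset, inv1, inv2):
        frags = [Fragment("chr1", 2_000_000, 3_000_000, "-" if inv1 else "+"),
                 Fragment("chr2", 5_000_000, 6_000_000, "-" if inv2 else "+")]
        tr = CoordinateTransform(frags)
        for f in frags:
            pos = f.start + offset
            assert tr.to_native(tr.to_reassembled(f.chrom, pos)) == (f.chrom, pos)

    def test_uncovered_position_rejected(self):
        tr = CoordinateTransform([Fragment("chr1", 0, 100, "+")])
        with pytest.raises(ValueError, match="not covered"):
            tr.to_reassembled("chr1", 200)

    def test_junction_shows_contiguous_decay(self, sv_genome):
        cm, _, ev = simulate_event(sv_genome)
        event = TranslocationEvent("chr1", BP_A, "left", "chr2", BP_B, "right",
                                   6, 10.0, True)
        rmap = reassemble_matrix(cm, event, sv_genome)
        assert junction_continuity(rmap) > 0.8

    def test_true_fusion_configuration_beats_all_alternatives(self, sv_genome):
        configs = list(itertools.product(["left", "right"], repeat=2))
        for fa, fb in configs:
            cm, _, _ = simulate_event(sv_genome, seed=20, fa=fa, fb=fb)
            stats = {}
            for ca, cb in configs:
                cand = TranslocationEvent("chr1", BP_A, ca, "chr2", BP_B, cb, 6, 10.0, True)
                stats[(ca, cb)] = junction_continuity(reassemble_matrix(cm, cand, sv_genome))
            assert max(stats, key=stats.get) == (fa, fb)

    def test_inverted_fragment_contacts_mirrored_against_oracle(self, sv_genome):
        # fragment B reverse-oriented: reassembled coordinate of a native
        # contact must match a brute-force per-position transform
        event = TranslocationEvent("chr1", 6_000_000, "left", "chr2", 5_000_000, "left",
                                   6, 10.0, True)
        cm, _, _ = simulate_event(sv_genome, seed=30, fa="left", fb="left")
        rmap = reassemble_matrix(cm, event, sv_genome)
        bs = 40_000
        rng = np.random.default_rng(1)
        tm = cm.matrix("chr1", "chr2").toarray()
        checked = 0
        for _ in range(200):
            if checked >= 50:
                break
            a_bin = int(rng.integers(100, 150))  # inside fragment A
            b_bin = int(rng.integers(80, 124))   # inside fragment B (inverted)
            v = tm[a_bin, b_bin]
            if v == 0:
                continue
            ra = rmap.transform.to_reassembled("chr1", a_bin * bs + bs // 2) // bs
            rb = rmap.transform.to_reassembled("chr2", b_bin * bs + bs // 2) // bs
            i, j = min(ra, rb), max(ra, rb)
            assert rmap.dense[i, j] == v
            checked += 1
        assert checked == 50


class TestNeoLoops:
    def test_planted_neo_loop_recovered_within_one_bin(self, sv_genome, sv_controls):
        neo = [(5_000_020, 6_000_020, 8.0)]
        cm, reads, ev = simulate_event(sv_genome, neo=neo)
        event = TranslocationEvent("chr1", BP_A, "left", "chr2", BP_B, "right", 6, 10.0, True)
        rmap = reassemble_matrix(cm, event, sv_genome)
        cmaps = [reassemble_matrix(c, event, sv_genome) for c in sv_controls]
        neos = detect_neo_loops(rmap, cmaps)
        assert len(neos) == 1
        (c1, s1, e1), (c2, s2, e2) = neos[0].native_anchor1, neos[0].native_anchor2
        assert c1 == "chr1" and abs(s1 - 5_000_000) <= 40_000
        assert c2 == "chr2" and abs(s2 - 6_000_000) <= 40_000
        assert neos[0].spans_junction

    def test_event_without_neo_loop_yields_none(self, sv_genome, sv_controls):
        cm, _, _ = simulate_event(sv_genome, seed=8)
        event = TranslocationEvent("chr1", BP_A, "left", "chr2", BP_B, "right", 6, 10.0, True)
        rmap = reassemble_matrix(cm, event, sv_genome)
        cmaps = [reassemble_matrix(c, event, sv_genome) for c in sv_controls]
        assert detect_neo_loops(rmap, cmaps) == []

    def test_preexisting_anchor_overlap_flagged(self, sv_genome, sv_controls):
        neo = [(5_000_020, 6_000_020, 8.0)]
        cm, _, _ = simulate_event(sv_genome, neo=neo)
        event = TranslocationEvent("chr1", BP_A, "left", "chr2", BP_B, "right", 6, 10.0, True)
        rmap = reassemble_matrix(cm, event, sv_genome)
        cmaps = [reassemble_matrix(c, event, sv_genome) for c in sv_controls]
        anchors = [("chr1", 4_990_000, 5_010_000)]
        neos = detect_neo_loops(rmap, cmaps, preexisting_anchors=anchors)
        assert neos and neos[0].on_preexisting_anchor


class TestAnnotation:
    genes = pd.DataFrame([
        {"name": "gA", "chrom": "chr1", "start": 6_163_456, "end": 6_200_000, "strand": "+"},
        {"name": "gB", "chrom": "chr2", "start": 4_000_000, "end": 4_100_000, "strand": "+"},
    ])

    def event(self):
        return TranslocationEvent("chr1", BP_A, "left", "chr2", BP_B, "right", 5, 10.0, True)

    def test_known_breakpoint_within_100kb_not_novel(self):
        known = pd.DataFrame({"chrom": ["chr1"], "pos": [BP_A + 50_000]})
        ann = annotate_event(self.event(), self.genes, known)
        assert ann["novel"] is False

    def test_distant_known_breakpoint_stays_novel(self):
        known = pd.DataFrame({"chrom": ["chr1"], "pos": [BP_A + 500_000]})
        ann = annotate_event(self.event(), self.genes, known)
        assert ann["novel"] is True

    def test_intergenic_breakpoint_reports_nearest_gene_distance(self):
        ann = annotate_event(self.event(), self.genes, None)
        assert ann["noncoding_a"] is True
        assert ann["nearest_gene_a"] == "gA"
        assert ann["nearest_gene_distance_a"] == 40_000

    def test_expression_status_up_requires_both_rules(self):
        expr = pd.DataFrame({
            "name": ["gA", "gB"],
            "case_fpkm": [3.0, 0.8],
            "ctrl1_fpkm": [1.0, 0.1],
            "ctrl2_fpkm": [1.0, 0.1],
        })
        ann = annotate_event(self.event(), self.genes, None, expression=expr,
                             sample="case", control_samples=["ctrl1", "ctrl2"])
        assert ann["nearest_gene_expression_a"] == "up"     # 3 > 1 and 3 >= 2x1
        assert ann["nearest_gene_expression_b"] == "unchanged"  # FPKM below 1

    def test_empty_gene_catalog_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_event(self.event(), pd.DataFrame(), None)
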