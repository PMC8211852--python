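"""Loop calling, APA, differential loops and CTCF orientation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neoloopscan.loops import (
    LoopCall,
    apa,
    call_loops,
    call_loops_at_resolution,
    classify_ctcf_orientation,
    differential_loops,
)
from neoloopscan.matrix import bin_contacts
from neoloopscan.simulate import StructureSpec, simulate_contact_map

from conftest import dense_to_matrix


class TestCalling:
    def test_null_map_yields_at_most_one_call(self, null_map):
        calls = call_loops_at_resolution(null_map, "chr1")
        assert len(calls) <= 1

    def test_planted_peaks_recovered(self, loop_calls, planted_loops):
        tp = sum(1 for (b1, b2, _) in planted_loops
                 if any(abs(c.bin1 - b1) <= 1 and abs(c.bin2 - b2) <= 1 for c in loop_calls))
        fp = sum(1 for c in loop_calls
                 if all(abs(c.bin1 - b1) > 1 or abs(c.bin2 - b2) > 1
                        for (b1, b2, _) in planted_loops))
        assert tp / len(planted_loops) >= 0.8
        assert (len(loop_calls) - fp) / len(loop_calls) >= 0.8

    def test_single_isolated_peak_called_exactly(self, loop_genome):
        spec = StructureSpec(loops={"chr1": [(700, 730, 5.0)]})
        recs = simulate_contact_map(loop_genome, spec, 10_000_000, seed=44)
        cm = bin_contacts(recs, loop_genome, 10_000)
        calls = call_loops_at_resolution(cm, "chr1")
        assert len(calls) == 1
        assert abs(calls[0].bin1 - 700) <= 1 and abs(calls[0].bin2 - 730) <= 1

    def test_scale_invariance_of_call_set(self, loop_map):
        calls1 = call_loops_at_resolution(loop_map, "chr1")
        scaled = loop_map.scaled(2.0)  # counts stay integral
        calls2 = call_loops_at_resolution(scaled, "chr1")
        assert {(c.bin1, c.bin2) for c in calls1} == {(c.bin1, c.bin2) for c in calls2}

    def test_nearby_peaks_merge_to_strongest(self, loop_genome):
        # two peaks 2 bins apart at 10-kb resolution, merge distance 20 kb
        spec = StructureSpec(loops={"chr1": [(600, 660, 6.0), (602, 662, 6.0)]})
        recs = simulate_contact_map(loop_genome, spec, 10_000_000, seed=45)
        cm = bin_contacts(recs, loop_genome, 10_000)
        calls = call_loops_at_resolution(cm, "chr1", merge_distance=20_000)
        near = [c for c in calls if abs(c.bin1 - 601) <= 2 and abs(c.bin2 - 661) <= 2]
        assert len(near) == 1
        assert near[0].merged

    def test_cross_resolution_reconciliation_keeps_finer_call(self, loop_genome):
        spec = StructureSpec(loops={"chr1": [(700, 760, 6.0)]})
        recs = simulate_contact_map(loop_genome, spec, 10_000_000, seed=46)
        fine = bin_contacts(recs, loop_genome, 10_000)
        coarse = bin_contacts(recs, loop_genome, 20_000)
        calls = call_loops({10_000: fine, 20_000: coarse}, "chr1",
                           merge_distances={10_000: 15_000, 20_000: 20_000})
        near = [c for c in calls if abs(c.bin1 * c.resolution - 7_000_000) <= 20_000]
        assert len(near) == 1
        assert near[0].resolution == 10_000


class TestApa:
    def test_center_enriched_on_planted_loops(self, loop_map, planted_loops):
        calls = [LoopCall("chr1", b1, b2, 10_000, 0, {}, 0, 0) for (b1, b2, _) in planted_loops]
        res = apa(loop_map, calls)
        assert res.center_score >= 1.5

    def test_center_near_one_on_random_anchors(self, null_map):
        rng = np.random.default_rng(8)
        n = 2000
        calls = []
        for _ in range(30):
            b1 = int(rng.integers(100, n - 200))
            calls.append(LoopCall("chr1", b1, b1 + int(rng.integers(25, 150)), 10_000, 0, {}, 0, 0))
        res = apa(null_map, calls)
        assert res.center_score == pytest.approx(1.0, abs=0.2)

    def test_duplicating_loop_list_leaves_matrix_unchanged(self, loop_map, planted_loops):
        calls = [LoopCall("chr1", b1, b2, 10_000, 0, {}, 0, 0) for (b1, b2, _) in planted_loops]
        r1 = apa(loop_map, calls)
        r2 = apa(loop_map, calls + calls)
        np.testing.assert_allclose(r1.matrix, r2.matrix)

    def test_diagonal_proximal_loops_excluded(self):
        cm = dense_to_matrix(np.full((60, 60), 2.0))
        near_diag = [LoopCall("c", 10, 15, 10, 0, {}, 0, 0)]  # separation < flank+2
        with pytest.raises(ValueError, match="eligible"):
            apa(cm, near_diag, flank=10)


class TestDifferential:
    def test_planted_gains_flagged_enhanced(self, diffloop_cohort):
        dl = differential_loops(diffloop_cohort["calls"], diffloop_cohort["mats"],
                                diffloop_cohort["groups"])
        gained = diffloop_cohort["gained"]
        tp = sum(1 for i in gained
                 if dl.iloc[i]["differential"] and dl.iloc[i]["direction"] == "enhanced")
        fp = sum(1 for i in range(len(dl)) if i not in gained and dl.iloc[i]["differential"])
        assert tp >= 15
        assert fp <= 2

    def test_label_permutation_null_controls_fdr(self, diffloop_cohort):
        null_mats = diffloop_cohort["null_mats"]
        names = list(null_mats)
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(5):
            order = rng.permutation(names)
            gr = {"g1": list(order[:4]), "g2": list(order[4:])}
            fracs.append(differential_loops(diffloop_cohort["calls"], null_mats, gr)
                         ["differential"].mean())
        assert np.median(fracs) <= 0.15

    @pytest.mark.parametrize("separation,expected", [(100_000, "short"), (200_000, "long")])
    def test_distance_stratum_assignment(self, separation, expected, diffloop_cohort):
        lp = LoopCall("chr1", 500, 500 + separation // 10_000, 10_000, 0, {}, 0, 0)
        dl = differential_loops([lp], diffloop_cohort["mats"], diffloop_cohort["groups"])
        assert dl.iloc[0]["stratum"] == expected


def _motif_row(chrom, pos, strand, score=10.0):
    return {"chrom": chrom, "start": pos, "end": pos + 20, "name": "m",
            "score": score, "strand": strand}


class TestCtcfOrientation:
    def _loop(self, a1=1000, a2=50_000, width=1000):
        return LoopCall("c", a1 // width, a2 // width, width, 0, {}, 0, 0)

    def oracle(self, s1, s2):
        if s1 is None and s2 is None:
            return "none"
        if s1 is None or s2 is None:
            return "single-anchor"
        return {("+", "-"): "convergent", ("-", "+"): "divergent"}.get((s1, s2), "tandem")

    def test_exhaustive_orientation_enumeration_matches_oracle(self):
        width = 1000
        for s1, s2 in itertools.product([None, "+", "-"], repeat=2):
            rows = []
            if s1:
                rows.append(_motif_row("c", 1200, s1))
            if s2:
                rows.append(_motif_row("c", 50_200, s2))
            motifs = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
            classes, _ = classify_ctcf_orientation([self._loop()], motifs)
            assert classes[0] == self.oracle(s1, s2), (s1, s2)

    def test_highest_scoring_motif_wins(self):
        motifs = pd.DataFrame([
            _motif_row("c", 1100, "-", score=5.0),
            _motif_row("c", 1500, "+", score=20.0),
            _motif_row("c", 50_200, "-", score=9.0),
        ])
        classes, _ = classify_ctcf_orientation([self._loop()], motifs)
        assert classes[0] == "convergent"

    def test_inverted_fragment_flips_strands_before_classification(self):
        motifs = pd.DataFrame([
            _motif_row("c", 1200, "+"),
            _motif_row("c", 50_200, "+"),  # inside the inverted interval
        ])
        classes, _ = classify_ctcf_orientation([self._loop()], motifs,
                                               flip_intervals=[("c", 40_000, 60_000)])
        assert classes[0] == "convergent"  # +/+ becomes +/- after the flip

    def test_summary_fractions_use_both_denominators(self):
        loops = [self._loop(), self._loop(100_000, 150_000)]
        motifs = pd.DataFrame([
            _motif_row("c", 1200, "+"), _motif_row("c", 50_200, "-"),
            _motif_row("c", 100_200, "+"),  # second loop: single anchor
        ])
        _, summary = classify_ctcf_orientation(loops, motifs)
        assert summary["convergent_of_both_anchored"] == 1.0
        assert summary["convergent_of_all"] == 0.5

    def test_unstranded_motifs_rejected(self):
        motifs = pd.DataFrame([{**_motif_row("c", 1200, "+"), "strand": None}])
        with pytest.raises(ValueError, match="strand"):
            classify_ctcf_orientation([self._loop()], motifs)
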