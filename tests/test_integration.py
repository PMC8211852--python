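"""Virtual 4C, region statistics, combined structural p and DEG association."""

import numpy as np
import pandas as pd
import pytest

from neoloopscan.genome import GenomeModel
from neoloopscan.integration import (
    V4cProfile,
    associate_degs,
    combined_structural_p,
    quantify_region_interactions,
    read_filter,
    virtual_4c,
)
from neoloopscan.matrix import bin_contacts, cis_depth_normalize
from neoloopscan.simulate import StructureSpec, simulate_contact_map

from conftest import dense_to_matrix


@pytest.fixture(scope="module")
def v4c_cohort():
    """2 vs 2 samples; the case group has an enhanced viewpoint-target loop."""
    g = GenomeModel({"chr1": 10_000_000}, binsize=10_000)
    view_bin, target_bin = 300, 380
    mats, groups = {}, {"control": [], "case": []}
    for gname, mult, off in (("control", 4.0, 0), ("case", 12.0, 10)):
        for si in range(2):
            spec = StructureSpec(loops={"chr1": [(view_bin, target_bin, mult)]})
            recs = simulate_contact_map(g, spec, 3_000_000, seed=off + si)
            s = f"{gname}_{si}"
            mats[s] = bin_contacts(recs, g, 10_000)
            groups[gname].append(s)
    return g, mats, groups, view_bin, target_bin


class TestV4c:
    def test_profile_equals_normalized_matrix_row(self, v4c_cohort):
        g, mats, groups, vb, _ = v4c_cohort
        sample = groups["control"][0]
        profiles, _ = virtual_4c({sample: mats[sample]}, "chr1", vb * 10_000 + 1)
        (normed,) = cis_depth_normalize([mats[sample]])
        row = normed.dense("chr1")[vb]
        rng = np.random.default_rng(0)
        for w in rng.integers(0, len(row), 20):
            assert profiles[0].values[w] == pytest.approx(row[w])

    def test_identical_groups_give_zero_difference(self, v4c_cohort):
        g, mats, groups, vb, _ = v4c_cohort
        s = groups["control"][0]
        _, diff = virtual_4c({"a": mats[s], "b": mats[s]}, "chr1", vb * 10_000 + 1,
                             groups={"g1": ["a"], "g2": ["b"]})
        np.testing.assert_allclose(diff, 0.0)

    def test_enhanced_loop_maximizes_group_difference_at_target(self, v4c_cohort):
        g, mats, groups, vb, target = v4c_cohort
        _, diff = virtual_4c(mats, "chr1", vb * 10_000 + 1,
                             groups={"case": groups["case"], "control": groups["control"]})
        # exclude the viewpoint's immediate neighborhood (decay-dominated)
        masked = diff.copy()
        masked[vb - 10 : vb + 11] = -np.inf
        assert abs(int(np.argmax(masked)) - target) <= 1

    def test_empty_viewpoint_rejected(self):
        dense = np.full((20, 20), 1.0)
        dense[5, :] = 0.0
        dense[:, 5] = 0.0
        cm = dense_to_matrix(dense)
        with pytest.raises(ValueError, match="empty|masked"):
            virtual_4c({"s": cm}, "c", 5 * 10 + 1)


class TestRegions:
    def test_region_score_is_mean_over_bins(self):
        prof = V4cProfile("c", 0, 10, np.array([0.0, 2.0, 4.0, 8.0]), "s")
        prof2 = V4cProfile("c", 0, 10, np.array([0.0, 2.0, 4.0, 8.0]), "t")
        out = quantify_region_interactions(
            {"a1": prof, "a2": prof2, "b1": prof, "b2": prof2},
            {"R": (10, 30)},  # bins 1 and 2 -> mean 3.0
            {"g1": ["a1", "a2"], "g2": ["b1", "b2"]})
        assert out.iloc[0]["mean_g1"] == pytest.approx(3.0)

    def test_twelve_regions_give_twelve_rows(self, v4c_cohort):
        g, mats, groups, vb, target = v4c_cohort
        profiles, _ = virtual_4c(mats, "chr1", vb * 10_000 + 1)
        by = {p.identity: p for p in profiles}
        regions = {f"E{k+1}": (k * 500_000, k * 500_000 + 100_000) for k in range(12)}
        out = quantify_region_interactions(by, regions, groups)
        assert len(out) == 12
        assert set(out["region"]) == set(regions)

    def test_planted_gain_region_has_smallest_fdr(self, v4c_cohort):
        g, mats, groups, vb, target = v4c_cohort
        profiles, _ = virtual_4c(mats, "chr1", vb * 10_000 + 1)
        by = {p.identity: p for p in profiles}
        regions = {f"E{k+1}": (k * 700_000 + 100_000, k * 700_000 + 200_000) for k in range(11)}
        regions["Etarget"] = (target * 10_000 - 10_000, target * 10_000 + 20_000)
        out = quantify_region_interactions(by, regions, groups)
        assert out.loc[out["fdr"].idxmin(), "region"] == "Etarget"


class TestCombinedP:
    def test_fisher_unit_pvalues_stay_one(self):
        t, _ = combined_structural_p(pd.Series({"g": 1.0}), pd.Series({"g": 1.0}))
        assert t.loc["g", "combined_p"] == pytest.approx(1.0)

    def test_fisher_matches_chi_square_closed_form(self):
        t, _ = combined_structural_p(pd.Series({"g": 0.05}), pd.Series({"g": 0.05}))
        assert t.loc["g", "combined_p"] == pytest.approx(0.0175, abs=0.0005)

    def test_missing_component_passes_through(self):
        t, _ = combined_structural_p(pd.Series({"g": 0.02}), pd.Series({"g": np.nan}))
        assert t.loc["g", "combined_p"] == pytest.approx(0.02)

    def test_monotone_in_each_input(self):
        base, _ = combined_structural_p(pd.Series({"g": 0.2}), pd.Series({"g": 0.3}))
        lower, _ = combined_structural_p(pd.Series({"g": 0.1}), pd.Series({"g": 0.3}))
        assert lower.loc["g", "combined_p"] <= base.loc["g", "combined_p"]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="\\(0, 1\\]"):
            combined_structural_p(pd.Series({"g": 0.0}), pd.Series({"g": 0.5}))

    @pytest.mark.parametrize("planted_r", [0.0, 0.4, 0.7])
    def test_planted_structure_expression_correlation_recovered(self, planted_r):
        rng = np.random.default_rng(3)
        n = 500
        idx = [f"g{i}" for i in range(n)]
        p1 = pd.Series(rng.uniform(1e-6, 1, n), index=idx)
        p2 = pd.Series(rng.uniform(1e-6, 1, n), index=idx)
        signs = pd.Series(rng.choice([-1.0, 1.0], n), index=idx)
        tab, _ = combined_structural_p(p1, p2, signs=signs)
        z = (tab["signed_score"] - tab["signed_score"].mean()) / tab["signed_score"].std()
        lfc = pd.Series(planted_r * z + np.sqrt(1 - planted_r**2) * rng.normal(size=n),
                        index=idx)
        _, r = combined_structural_p(p1, p2, expression_logfc=lfc, signs=signs)
        assert r == pytest.approx(planted_r, abs=0.1)


class TestAssociation:
    def test_read_filter_excludes_low_count_genes(self):
        counts = pd.DataFrame({
            "s1": [4, 10, 1], "s2": [4, 10, 1], "s3": [10, 10, 1], "s4": [10, 10, 1],
        })
        keep = read_filter(counts)
        assert keep.tolist() == [False, True, False]  # 50% low; ok; mean < 2

    def _cohort(self, rng, n_genes=120, n_coupled=50, shift=1.0):
        binsize = 40_000
        genes = pd.DataFrame({
            "name": [f"g{i}" for i in range(n_genes)],
            "chrom": "chr1",
            "start": np.arange(n_genes) * 200_000,
            "end": np.arange(n_genes) * 200_000 + 50_000,
            "strand": "+",
        })
        coupled = set(range(n_coupled))
        lfc = rng.normal(0, 0.3, n_genes)
        lfc[list(coupled)] += shift
        expr = genes.copy()
        expr["logFC"] = lfc
        expr["fdr"] = 0.001
        switch_rows = [{"chrom": "chr1", "bin": (i * 200_000) // binsize,
                        "direction": "B-to-A"} for i in coupled]
        return genes, expr, pd.DataFrame(switch_rows), binsize, coupled

    def test_gene_on_b_to_a_bin_classified(self):
        rng = np.random.default_rng(0)
        genes, expr, switches, binsize, coupled = self._cohort(rng, n_genes=10, n_coupled=2)
        assoc, _ = associate_degs(expr, genes, switches=switches, binsize=binsize)
        assert assoc.iloc[0]["classes"] == ["B-to-A"]
        assert assoc.iloc[9]["classes"] == ["no structural change"]

    def test_planted_up_coupling_detected_by_one_sided_wilcoxon(self):
        rng = np.random.default_rng(1)
        genes, expr, switches, binsize, coupled = self._cohort(rng)
        assoc, tests = associate_degs(expr, genes, switches=switches, binsize=binsize)
        row = tests[tests["class"] == "B-to-A"].iloc[0]
        assert row["p"] < 0.01
        assert row["median_logFC"] > 0

    def test_every_gene_gets_exactly_one_classification_list(self):
        rng = np.random.default_rng(2)
        genes, expr, switches, binsize, _ = self._cohort(rng, n_genes=40, n_coupled=10)
        assoc, _ = associate_degs(expr, genes, switches=switches, binsize=binsize)
        assert len(assoc) == len(expr)
        assert assoc["classes"].apply(lambda c: len(c) >= 1).all()

    def test_gene_universe_mismatch_reported(self):
        genes = pd.DataFrame({"name": ["a"], "chrom": ["chr1"], "start": [0],
                              "end": [1000], "strand": ["+"]})
        expr = pd.DataFrame({"name": ["a", "zz"], "chrom": "chr1", "start": 0,
                             "end": 1000, "logFC": [0.0, 1.0]})
        with pytest.raises(ValueError, match="absent"):
            associate_degs(expr, genes)
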