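import numpy as np
import pytest
from scipy import stats

from cladeshift.codon import CodonAlignment
from cladeshift.models import (
    CodonModelSpec,
    classify_sites,
    fit_gtr_branch_lengths,
    fit_model,
)
from cladeshift.posgc import (
    branch_ratio_analysis,
    class2a_gc_summary,
    gc_content,
    one_way_anova,
    split_codon_positions,
)
from cladeshift.simulate import simulate_codon_alignment
from cladeshift.trees import UnitPartition, label_branches, parse_newick


class TestPositionSplit:
    def test_nine_columns_split_into_three(self):
        aln = CodonAlignment(["x", "y"], ["ATGCCGTTA", "ATGCCGTTC"])
        p1, p2, p3 = split_codon_positions(aln)
        assert p1.length == p2.length == p3.length == 3
        assert p2.sequence("x") == "TCT"

    def test_round_trip_recombines(self):
        aln = CodonAlignment(["x", "y"], ["ATGCCGTTA", "GTGACGTTC"])
        p1, p2, p3 = split_codon_positions(aln)
        rebuilt = ["".join(a + b + c for a, b, c in
                           zip(p1.seqs[i], p2.seqs[i], p3.seqs[i]))
                   for i in range(2)]
        assert rebuilt == aln.seqs

    def test_second_position_of_atgatg(self):
        aln = CodonAlignment(["x"], ["ATGATG"])
        assert split_codon_positions(aln)[1].sequence("x") == "TT"


class TestAnova:
    def test_equal_means_give_zero_f(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = one_way_anova(values, groups)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_df_structure_21_values_4_groups(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=21)
        groups = np.array(["a"] * 6 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5)
        res = one_way_anova(values, groups)
        assert (res.df1, res.df2) == (3, 17)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 8), rng.normal(0.7, 1, 11)
        res = one_way_anova(np.concatenate([x, y]),
                            np.array(["x"] * 8 + ["y"] * 11))
        t = stats.ttest_ind(x, y, equal_var=True)
        assert res.F == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        samples = [rng.normal(m, 1, 7) for m in (0, 0.5, 1.0)]
        res = one_way_anova(np.concatenate(samples),
                            np.repeat(["a", "b", "c"], 7))
        ref = stats.f_oneway(*samples)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        base = one_way_anova(values, groups)
        shifted = one_way_anova(values + 100.0, groups)
        scaled = one_way_anova(values * 7.0, groups)
        assert shifted.F == pytest.approx(base.F)
        assert scaled.r_squared == pytest.approx(base.r_squared)

    def test_type_one_error_at_nominal_level(self):
        # null: both branch groups share one ratio distribution
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(300):
            values = rng.gamma(2.0, 0.1, size=40)
            groups = np.array(["bg"] * 34 + ["fg"] * 6)
            if one_way_anova(values, groups).p_value < 0.05:
                rejections += 1
        # binomial band around 5% of 300
        assert rejections <= stats.binom.ppf(0.999, 300, 0.05)


class TestBranchRatios:
    def test_identical_trees_give_unit_ratios(self, quartet):
        tree, _, lab = quartet
        table = branch_ratio_analysis(tree, tree, lab)
        assert np.allclose(table.table["ratio"], 1.0)
        assert table.anova.F == pytest.approx(0.0, abs=1e-12)

    def test_topology_mismatch_rejected(self, quartet):
        tree, _, lab = quartet
        other = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
        with pytest.raises(ValueError, match="topology"):
            branch_ratio_analysis(tree, other, lab)

    def test_foreground_elevation_detected(self, insect_tree):
        # 3rd-position lengths common to both groups; 2nd-position lengths
        # elevated on among-unit branches (the published 0.29 vs 0.13 regime)
        tree, partition = insect_tree
        lab = label_branches(tree, partition)
        rng = np.random.default_rng(5)
        l3 = np.abs(tree.lengths * (1 + rng.normal(0, 0.1, tree.n_nodes)))
        ratio_true = np.where(lab.foreground, 0.29, 0.13)
        l2 = l3 * ratio_true * (1 + rng.normal(0, 0.15, tree.n_nodes))
        t2 = tree.with_lengths(l2)
        t3 = tree.with_lengths(l3)
        table = branch_ratio_analysis(t2, t3, lab)
        assert table.group_mean("foreground") > table.group_mean("background")
        assert table.anova.p_value < 0.05
        assert table.anova.df1 == 1 and table.anova.df2 == 38

    def test_floored_denominators_flagged(self, quartet):
        tree, _, lab = quartet
        zero3 = tree.with_lengths(np.zeros(tree.n_nodes))
        table = branch_ratio_analysis(tree, zero3, lab)
        assert table.table["floored"].all()
        assert np.isfinite(table.table["ratio"]).all()


class TestGC:
    def test_pure_gc_and_pure_at(self):
        aln = CodonAlignment(["g", "a"], ["GCGCGC", "ATATAT"])
        prof = gc_content(aln)
        assert prof.loc["g"].tolist() == [100.0, 100.0, 100.0, 100.0]
        assert prof.loc["a"].tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_positional_recombination_is_exact(self):
        rng = np.random.default_rng(6)
        codons = ["ATG", "GCC", "TTA", "CGG", "AAT"]
        seqs = ["".join(rng.choice(codons, 30)) for _ in range(3)]
        aln = CodonAlignment(["s1", "s2", "s3"], seqs)
        prof = gc_content(aln)
        # full-sequence GC is the equal-weight mean of the three positions
        assert np.allclose(prof[["gc1", "gc2", "gc3"]].mean(axis=1),
                           prof["gc_all"])

    def test_gaps_excluded_from_denominator(self):
        aln = CodonAlignment(["x"], ["GC-GC-"])
        prof = gc_content(aln)
        assert prof.loc["x", "gc_all"] == 100.0

    def test_empty_subset_warns(self, caplog):
        aln = CodonAlignment(["x"], ["ATGATG"])
        with caplog.at_level("WARNING", logger="cladeshift"):
            prof = gc_content(aln, site_mask=np.zeros(2, dtype=bool))
        assert prof.empty
        assert "empty codon subset" in caplog.text

    def test_class2a_subset_profile(self, quartet, freqs):
        tree, _, lab = quartet
        truth = CodonModelSpec(3, kappa=2.0, omega0=0.05, p0=0.5, p1=0.1)
        sim = simulate_codon_alignment(tree, lab, truth, 200, seed=12,
                                       freqs=freqs)
        fit = fit_model(sim.alignment, tree, lab, 3, freqs=freqs,
                        kappa=truth.kappa, optimize_scale=False, n_starts=1,
                        seed=0)
        cls = classify_sites(fit, threshold=0.5)
        prof = class2a_gc_summary(sim.alignment, cls, threshold=0.5)
        if not prof.empty:
            assert prof.values.min() >= 0 and prof.values.max() <= 100


class TestPositionPipeline:
    def test_branch_site_signal_shows_in_position_ratios(self, freqs):
        # end-to-end surrogate check: simulate under the branch-site model,
        # fit GTR lengths to 2nd- and 3rd-position splits, and confirm the
        # foreground 2nd:3rd ratio exceeds the background one
        tree = parse_newick(
            "(((a1:.2,a2:.2):.4,(b1:.2,b2:.2):.4):.3,"
            "((c1:.2,c2:.2):.4,(d1:.2,d2:.2):.4):.3);")
        part = UnitPartition({t: t[0].upper() for t in tree.tip_name.values()})
        lab = label_branches(tree, part)
        truth = CodonModelSpec(3, kappa=2.0, omega0=0.02, p0=0.55, p1=0.05)
        sim = simulate_codon_alignment(tree, lab, truth, 600, seed=13,
                                       freqs=freqs)
        _, p2, p3 = split_codon_positions(sim.alignment)
        t2, _ = fit_gtr_branch_lengths(p2, tree)
        t3, _ = fit_gtr_branch_lengths(p3, tree)
        table = branch_ratio_analysis(t2, t3, lab)
        assert table.group_mean("foreground") > table.group_mean("background")
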