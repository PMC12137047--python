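import numpy as np
import pytest

from cladeshift.codon import Alignment, CodonAlignment
from cladeshift.models import (
    CodonLikelihood,
    CodonModelSpec,
    classify_sites,
    ds_branch_lengths,
    fit_gtr_branch_lengths,
    fit_model,
    log_likelihood,
    mixture_layout,
)
from cladeshift.simulate import simulate_codon_alignment
from cladeshift.trees import BranchLabeling, UnitPartition, label_branches, parse_newick

from conftest import brute_force_loglik, make_fit


class TestMixtureLayout:
    def test_branch_site_expansion_matches_reported_ratios(self):
        # a model-3 parameterization consistent with the published estimates:
        # p2a/p2b must equal p0/p1 under the constrained expansion
        spec = CodonModelSpec(3, omega0=0.040, p0=0.730, p1=0.043)
        mix = mixture_layout(spec)
        p = dict(zip(mix.labels, mix.proportions))
        assert p["2a"] / p["2b"] == pytest.approx(0.730 / 0.043, rel=1e-9)
        assert p["2a"] == pytest.approx(0.214, abs=5e-4)
        assert p["2b"] == pytest.approx(0.013, abs=5e-4)
        # foreground omega of the switching classes is pinned to 1 in model 3
        assert mix.omega_fg[2] == 1.0 and mix.omega_fg[3] == 1.0

    def test_site_model_classes(self):
        mix = mixture_layout(CodonModelSpec(1, omega0=0.041, p0=0.94))
        assert mix.as_rows() == [("0", 0.94, 0.041, 0.041),
                                 ("1", pytest.approx(0.06), 1.0, 1.0)]

    @pytest.mark.parametrize("spec", [
        CodonModelSpec(1, p0=0.5, omega0=0.2),
        CodonModelSpec(2, p0=0.4, p1=0.3, omega0=0.2, omega2=3.0),
        CodonModelSpec(3, p0=0.6, p1=0.1, omega0=0.1),
        CodonModelSpec(4, p0=0.6, p1=0.1, omega0=0.1, omega2=1.8),
    ])
    def test_proportions_sum_to_one(self, spec):
        assert mixture_layout(spec).proportions.sum() == pytest.approx(1, abs=1e-12)

    def test_free_parameter_counts(self):
        specs = {1: CodonModelSpec(1), 2: CodonModelSpec(2, p1=0.1, omega2=2.0),
                 3: CodonModelSpec(3, p1=0.1),
                 4: CodonModelSpec(4, p1=0.1, omega2=2.0)}
        assert {m: s.n_free_parameters for m, s in specs.items()} == \
            {1: 2, 2: 4, 3: 3, 4: 4}

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            mixture_layout(CodonModelSpec(2, p0=0.8, p1=0.5, omega2=2.0))


class TestLikelihood:
    def test_zero_branch_identical_sequences_closed_form(self, freqs):
        tree = parse_newick("(a:0,b:0);")
        aln = CodonAlignment(["a", "b"], ["ATGAAA", "ATGAAA"])
        spec = CodonModelSpec(1, kappa=2.0, omega0=0.1, p0=0.7)
        _, per_site = log_likelihood(aln, tree, None, spec, freqs=freqs)
        expect = [np.log(freqs.pi[freqs.code.index("ATG")]),
                  np.log(freqs.pi[freqs.code.index("AAA")])]
        assert np.allclose(per_site, expect, atol=1e-12)

    @pytest.mark.parametrize("model_id,extra", [
        (1, {}), (2, {"p1": 0.2, "omega2": 3.0}),
        (3, {"p1": 0.1}), (4, {"p1": 0.1, "omega2": 2.5}),
    ])
    def test_pruning_equals_brute_force(self, quartet, quartet_sim, freqs,
                                        model_id, extra):
        tree, _, labeling = quartet
        aln = quartet_sim.alignment
        spec = CodonModelSpec(model_id, kappa=2.5, omega0=0.07, p0=0.6, **extra)
        _, per_site = log_likelihood(aln, tree, labeling, spec, freqs=freqs)
        oracle = brute_force_loglik(aln, tree, labeling, spec, freqs)
        assert np.abs(per_site - oracle).max() < 1e-8

    def test_root_placement_irrelevant_for_site_models(self, freqs):
        # sliding the root along the central branch leaves the likelihood of
        # a reversible site model unchanged (pulley principle)
        aln = CodonAlignment(["a", "b", "c", "d"],
                             ["ATGAAATTT", "ATGAAGTTC", "ACGAAATTT", "ATGCAATTT"])
        spec = CodonModelSpec(1, kappa=2.0, omega0=0.1, p0=0.8)
        versions = ["((a:.3,b:.5):.1,(c:.4,d:.2):.5);",
                    "((a:.3,b:.5):.4,(c:.4,d:.2):.2);",
                    "((a:.3,b:.5):.6,(c:.4,d:.2):0);"]
        totals = [log_likelihood(aln, parse_newick(v), None, spec,
                                 freqs=freqs)[0] for v in versions]
        assert np.ptp(totals) < 1e-8

    def test_all_background_model3_collapses_to_model1(self, quartet_sim, freqs):
        # with no foreground branches, classes 2a/2b merge into 0/1
        aln, tree = quartet_sim.alignment, quartet_sim.tree
        lab = BranchLabeling.all_background(tree)
        p0, p1, w0 = 0.6, 0.1, 0.07
        m3 = CodonModelSpec(3, kappa=2.5, omega0=w0, p0=p0, p1=p1)
        mix3 = mixture_layout(m3)
        p = dict(zip(mix3.labels, mix3.proportions))
        m1 = CodonModelSpec(1, kappa=2.5, omega0=w0, p0=p["0"] + p["2a"])
        l3, _ = log_likelihood(aln, tree, lab, m3, freqs=freqs)
        l1, _ = log_likelihood(aln, tree, lab, m1, freqs=freqs)
        assert l3 == pytest.approx(l1, abs=1e-8)

    def test_column_order_irrelevant(self, quartet, quartet_sim, freqs):
        # pattern compression: permuting codon columns preserves the total
        tree, _, labeling = quartet
        aln = quartet_sim.alignment
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_codons)
        shuffled = CodonAlignment(
            aln.names,
            ["".join(s[3 * c: 3 * c + 3] for c in perm) for s in aln.seqs])
        spec = CodonModelSpec(3, kappa=2.5, omega0=0.05, p0=0.6, p1=0.1)
        t1, _ = log_likelihood(aln, tree, labeling, spec, freqs=freqs)
        t2, _ = log_likelihood(shuffled, tree, labeling, spec, freqs=freqs)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_taxa_mismatch_rejected(self, quartet, freqs):
        tree, _, _ = quartet
        aln = CodonAlignment(["a", "b"], ["ATG", "ATG"])
        with pytest.raises(ValueError, match="do not match"):
            CodonLikelihood(aln, tree, None, freqs)


@pytest.fixture(scope="module")
def eight_tip_sim(freqs):
    tree = parse_newick(
        "(((a1:.2,a2:.2):.3,(b1:.2,b2:.2):.3):.2,"
        "((c1:.2,c2:.2):.3,(d1:.2,d2:.2):.3):.2);")
    part = UnitPartition({t: t[0].upper() for t in tree.tip_name.values()})
    lab = label_branches(tree, part)
    truth = CodonModelSpec(3, kappa=2.0, omega0=0.05, p0=0.65, p1=0.1)
    sim = simulate_codon_alignment(tree, lab, truth, 400, seed=21, freqs=freqs)
    return tree, lab, truth, sim


class TestFitting:
    def test_nesting_and_constraints(self, eight_tip_sim, freqs):
        tree, lab, truth, sim = eight_tip_sim
        fits = {}
        for mid in (1, 2, 3, 4):
            fits[mid] = fit_model(sim.alignment, tree, lab, mid,
                                  freqs=freqs, kappa=truth.kappa,
                                  optimize_scale=False, n_starts=2, seed=1)
        assert fits[3].spec.omega2 == 1.0
        assert fits[2].log_likelihood >= fits[1].log_likelihood - 1e-4
        assert fits[4].log_likelihood >= fits[3].log_likelihood - 1e-4

    def test_recovers_generating_parameters(self, eight_tip_sim, freqs):
        tree, lab, truth, sim = eight_tip_sim
        fit = fit_model(sim.alignment, tree, lab, 3, freqs=freqs,
                        kappa=truth.kappa, optimize_scale=False,
                        n_starts=2, seed=2)
        assert fit.spec.omega0 == pytest.approx(truth.omega0, abs=0.03)
        assert fit.spec.p0 == pytest.approx(truth.p0, abs=0.15)

    def test_classification_separates_true_classes(self, eight_tip_sim, freqs):
        tree, lab, truth, sim = eight_tip_sim
        fit = fit_model(sim.alignment, tree, lab, 3, freqs=freqs,
                        kappa=truth.kappa, optimize_scale=False,
                        n_starts=2, seed=3)
        cls = classify_sites(fit)
        assert np.allclose(cls.posterior.sum(axis=1), 1.0, atol=1e-9)
        true2a = sim.class_index == 2
        true0 = sim.class_index == 0
        assert cls.prob("2a")[true2a].mean() > cls.prob("2a")[true0].mean()

    def test_site_model_fit_cannot_be_classified(self, eight_tip_sim, freqs):
        tree, lab, truth, sim = eight_tip_sim
        fit = fit_model(sim.alignment, tree, lab, 1, freqs=freqs,
                        kappa=truth.kappa, optimize_scale=False,
                        n_starts=1, seed=0)
        with pytest.raises(ValueError, match="branch-site"):
            classify_sites(fit)


class TestDsBranchLengths:
    def test_zero_branch_and_linearity(self, quartet, quartet_sim, freqs):
        tree, _, labeling = quartet
        lengths = tree.lengths.copy()
        lengths[0] = 0.0
        t0 = tree.with_lengths(lengths)
        fit = make_fit(3, -1.0, tree=t0,
                       labeling=BranchLabeling(t0, labeling.foreground),
                       freqs=freqs)
        ds_tree, dmax = ds_branch_lengths(fit)
        assert ds_tree.lengths[0] == 0.0
        fit2 = make_fit(3, -1.0, tree=t0.scaled(2.0),
                        labeling=BranchLabeling(t0, labeling.foreground),
                        freqs=freqs)
        _, dmax2 = ds_branch_lengths(fit2)
        assert dmax2 == pytest.approx(2 * dmax, rel=1e-9)

    def test_simulation_recovery_of_max_ds(self, freqs):
        # truth-side dS from the generating parameters vs the dS recovered
        # from a refit on simulated data
        tree = parse_newick(
            "(((a1:.3,a2:.3):.4,(b1:.3,b2:.3):.4):.3,"
            "((c1:.3,c2:.3):.4,(d1:.3,d2:.3):.4):.3);")
        part = UnitPartition({t: t[0].upper() for t in tree.tip_name.values()})
        lab = label_branches(tree, part)
        truth = CodonModelSpec(1, kappa=2.0, omega0=0.05, p0=0.8)
        sim = simulate_codon_alignment(tree, lab, truth, 800, seed=5,
                                       freqs=freqs)
        truth_fit = make_fit(1, -1.0, omega0=truth.omega0, p0=truth.p0,
                             tree=tree, labeling=lab, freqs=freqs)
        _, ds_true = ds_branch_lengths(truth_fit)
        fit = fit_model(sim.alignment, tree, lab, 1, freqs=freqs,
                        n_starts=2, seed=6)
        _, ds_hat = ds_branch_lengths(fit)
        assert ds_hat == pytest.approx(ds_true, rel=0.15)


class TestGTR:
    def test_identical_sequences_zero_lengths(self):
        aln = Alignment(["a", "b", "c"], ["ACGTACGT"] * 3)
        tree = parse_newick("((a:1,b:1):1,c:1);")
        fitted, info = fit_gtr_branch_lengths(aln, tree)
        assert np.nanmax(fitted.lengths[fitted.branches()]) < 1e-6

    def test_two_taxon_jc_closed_form(self):
        rng = np.random.default_rng(4)
        n = 3000
        a = rng.integers(0, 4, size=n)
        # mutate ~12% of sites to a different base
        flip = rng.random(n) < 0.12
        b = np.where(flip, (a + rng.integers(1, 4, size=n)) % 4, a)
        nts = np.array(list("ACGT"))
        aln = Alignment(["x", "y"], ["".join(nts[a]), "".join(nts[b])])
        tree = parse_newick("(x:0.05,y:0.05);")
        fitted, info = fit_gtr_branch_lengths(aln, tree, equal_rates=True,
                                              uniform_freqs=True)
        p = (a != b).mean()
        d = -0.75 * np.log(1 - 4 * p / 3)
        total = fitted.lengths[fitted.branches()].sum()
        assert total == pytest.approx(d, abs=1e-4)
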