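import math

import numpy as np
import pytest

from bovimito import (MultiAlignment, RootedTree, SubstitutionModel,
                      bayes_factor, clock_lrt, harmonic_mean_loglik,
                      log_likelihood, optimize_branch_lengths, read_trace)
from bovimito.likelihood import ZeroLikelihoodSite, alrt_support
from bovimito.simulate import SimulationConfig, simulate


def jc_prob_same(t: float) -> float:
    return 0.25 + 0.75 * math.exp(-4 * t / 3)


def jc_prob_diff(t: float) -> float:
    return 0.25 - 0.25 * math.exp(-4 * t / 3)


class TestModel:
    def test_p0_is_identity_and_rows_sum_to_one(self):
        m = SubstitutionModel(
            rates={"AC": 0.7, "AG": 12, "AT": 1.3, "CG": 0.4, "CT": 9,
                   "GT": 1.0},
            pi=np.array([0.35, 0.25, 0.1, 0.3]), alpha=0.5, n_categories=4)
        assert np.allclose(m.transition_matrices(0.0), np.eye(4), atol=1e-12)
        for t in (0.001, 0.1, 1.0, 10.0):
            P = m.transition_matrices(t)
            assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)
            assert (P >= 0).all()

    def test_rate_matrix_normalized(self):
        m = SubstitutionModel(pi=np.array([0.4, 0.3, 0.2, 0.1]))
        Q = m.q_matrix()
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.dot(m.pi, np.diag(Q)) == pytest.approx(1.0)

    def test_category_rates_mean_one(self):
        for alpha in (0.1, 0.867, 5.0):
            m = SubstitutionModel(alpha=alpha, n_categories=4)
            r = m.category_rates()
            assert r.mean() == pytest.approx(1.0)
            assert (np.diff(r) > 0).all()

    def test_kappa_for_transition_heavy_model(self):
        m = SubstitutionModel(
            rates={"AC": 1, "AG": 40, "AT": 1, "CG": 1, "CT": 40, "GT": 1},
            pi=np.full(4, 0.25))
        # kappa = (s_AG + s_CT) / (4 transversion rates) at equal frequencies
        assert m.kappa == pytest.approx(80 / 4)

    def test_stationarity(self):
        m = SubstitutionModel(
            rates={"AC": 1, "AG": 6, "AT": 2, "CG": 1, "CT": 7, "GT": 1},
            pi=np.array([0.3, 0.2, 0.2, 0.3]))
        P = m.transition_matrices(0.7)[0]
        assert np.allclose(m.pi @ P, m.pi, atol=1e-12)


class TestLogLikelihood:
    def test_single_site_zero_branch(self):
        t = RootedTree.from_newick("(a:0.0,b:0.0);")
        aln = MultiAlignment(["a", "b"], ["A", "A"], "a")
        lnl = log_likelihood(aln, t, SubstitutionModel.jc())
        assert lnl == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("t_total", [0.05, 0.3, 1.2])
    def test_two_taxon_jc_closed_form(self, t_total):
        tree = RootedTree.from_newick(f"(a:{t_total / 2},b:{t_total / 2});")
        m = SubstitutionModel.jc()
        same = log_likelihood(MultiAlignment(["a", "b"], ["A", "A"], "a"),
                              tree, m)
        diff = log_likelihood(MultiAlignment(["a", "b"], ["A", "C"], "a"),
                              tree, m)
        assert math.exp(same) == pytest.approx(0.25 * jc_prob_same(t_total),
                                               abs=1e-10)
        assert math.exp(diff) == pytest.approx(0.25 * jc_prob_diff(t_total),
                                               abs=1e-10)

    def test_gap_is_missing_data(self):
        tree = RootedTree.from_newick("(a:0.1,b:0.1);")
        aln = MultiAlignment(["a", "b"], ["A", "-"], "a")
        lnl = log_likelihood(aln, tree, SubstitutionModel.jc())
        assert lnl == pytest.approx(math.log(0.25), abs=1e-12)

    def test_compression_invariance(self, preset_run):
        _, _, aln, _ = preset_run
        sub = aln.subset_columns(list(range(0, aln.length, 8)))
        tree = RootedTree.from_newick(
            "(BRS:0.01,(wisent:0.02,(bison:0.01,yak:0.01):0.01):0.01);")
        m = SubstitutionModel.from_alignment(sub, alpha=0.9)
        l1 = log_likelihood(sub, tree, m, compress=True)
        l2 = log_likelihood(sub, tree, m, compress=False)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_rerooting_invariance(self):
        """A reversible model gives the same likelihood for any rooting of
        the same unrooted tree."""
        rng = np.random.default_rng(2)
        cols = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(200)]
        rows = ["".join(c[i] for c in cols) for i in range(4)]
        aln = MultiAlignment(["a", "b", "c", "d"], rows, "a")
        m = SubstitutionModel(
            rates={"AC": 1, "AG": 5, "AT": 1, "CG": 1, "CT": 5, "GT": 1},
            pi=np.array([0.3, 0.25, 0.15, 0.3]), alpha=0.8, n_categories=4)
        t1 = RootedTree.from_newick(
            "((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.05);")
        # same unrooted tree, rooted along the pendant edge to a
        t2 = RootedTree.from_newick(
            "(a:0.02,(b:0.2,(c:0.15,d:0.1):0.1):0.08);")
        assert log_likelihood(aln, t1, m) == pytest.approx(
            log_likelihood(aln, t2, m), abs=1e-8)

    def test_impossible_site_errors(self):
        tree = RootedTree.from_newick("(a:0.0,b:0.0);")
        aln = MultiAlignment(["a", "b"], ["A", "C"], "a")
        with pytest.raises(ZeroLikelihoodSite, match="column 1"):
            log_likelihood(aln, tree, SubstitutionModel.jc())


class TestOptimization:
    def test_two_taxon_matches_analytic_jc_distance(self, jc_pair_50kb):
        aln, _ = jc_pair_50kb
        tree = RootedTree.from_newick("(a:0.01,b:0.01);")
        opt, _, _ = optimize_branch_lengths(aln, tree, SubstitutionModel.jc())
        total = sum(n.length for n in opt.postorder() if n is not opt.root)
        p = sum(x != y for x, y in zip(*aln.rows)) / aln.length
        analytic = -0.75 * math.log(1 - 4 * p / 3)
        assert total == pytest.approx(analytic, abs=1e-6)

    def test_branch_length_recovery_within_10pct(self):
        tree = RootedTree.from_newick(
            "(a:0.05,(b:0.03,(c:0.02,d:0.04):0.03):0.02);")
        cfg = SimulationConfig(tree=tree, model=SubstitutionModel.jc(),
                               genome_length=50000, seed=7)
        _, aln, truth = simulate(cfg)
        start = tree.copy()
        for n in start.postorder():
            if n is not start.root:
                n.length = 0.01
        opt, _, _ = optimize_branch_lengths(aln, start,
                                            SubstitutionModel.jc())
        root_children = opt.root.children
        root_edge = sum(c.length for c in root_children)
        true_root_edge = sum(
            truth.branch_lengths[tree.branch_id(c)]
            for c in tree.root.children)
        assert root_edge == pytest.approx(true_root_edge, rel=0.10)
        for n in opt.postorder():
            if n is opt.root or n in root_children:
                continue
            bid = opt.branch_id(n)
            true = truth.branch_lengths[bid]
            if true >= 0.01:
                assert n.length == pytest.approx(true, rel=0.10)

    def test_restart_from_optimum_is_fixed_point(self, jc_pair_50kb):
        aln, _ = jc_pair_50kb
        tree = RootedTree.from_newick("(a:0.01,b:0.01);")
        opt, m, lnl1 = optimize_branch_lengths(aln, tree,
                                               SubstitutionModel.jc())
        _, _, lnl2 = optimize_branch_lengths(aln, opt, m)
        assert abs(lnl2 - lnl1) < 1e-5


class TestClockLRT:
    def test_identical_sequences_statistic_zero(self):
        aln = MultiAlignment(["a", "b", "c"], ["ACGTACGTAC"] * 3, "a")
        tree = RootedTree.from_newick("(a:0.1,(b:0.1,c:0.1):0.1);")
        res = clock_lrt(aln, tree, SubstitutionModel.jc())
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == 1.0
        assert res.df == 1

    def test_statistic_nonnegative_over_random_datasets(self):
        tree = RootedTree.from_newick(
            "((a:0.03,b:0.01):0.01,(c:0.02,d:0.02):0.01);")
        for seed in range(5):
            cfg = SimulationConfig(tree=tree, model=SubstitutionModel.jc(),
                                   genome_length=1500, seed=400 + seed)
            _, aln, _ = simulate(cfg)
            res = clock_lrt(aln, tree, SubstitutionModel.jc())
            assert res.statistic >= 0.0
            assert res.clock_tree.is_ultrametric(tol=1e-6)

    def test_rate_heterogeneity_detected(self):
        """A threefold-faster terminal branch is flagged at 10 kb."""
        tree = RootedTree.from_newick(
            "((a:0.06,b:0.02):0.02,(c:0.02,d:0.02):0.02);")
        rejected = 0
        for seed in range(10):
            cfg = SimulationConfig(tree=tree, model=SubstitutionModel.jc(),
                                   genome_length=10000, seed=3000 + seed)
            _, aln, _ = simulate(cfg)
            res = clock_lrt(aln, tree, SubstitutionModel.jc())
            rejected += res.p_value < 0.05
        assert rejected >= 9

    def test_too_few_taxa_errors(self):
        aln = MultiAlignment(["a", "b"], ["ACGT", "ACGT"], "a")
        tree = RootedTree.from_newick("(a:0.1,b:0.1);")
        with pytest.raises(ValueError):
            clock_lrt(aln, tree, SubstitutionModel.jc())


class TestALRT:
    def test_resolved_quartet_high_support(self):
        tree = RootedTree.from_newick(
            "((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1);")
        cfg = SimulationConfig(tree=tree, model=SubstitutionModel.jc(),
                               genome_length=10000, seed=5)
        _, aln, _ = simulate(cfg)
        sup = alrt_support(aln, tree, SubstitutionModel.jc())
        assert sup["a+b"] > 0.99

    def test_star_like_data_low_support(self):
        tree = RootedTree.from_newick(
            "((a:0.05,b:0.05):0.0001,(c:0.05,d:0.05):0.0001);")
        cfg = SimulationConfig(tree=tree, model=SubstitutionModel.jc(),
                               genome_length=2000, seed=8)
        _, aln, _ = simulate(cfg)
        sup = alrt_support(aln, tree, SubstitutionModel.jc())
        assert sup["a+b"] < 0.95

    def test_pendant_unrooted_edge_reported_na(self, preset_run):
        _, _, aln, _ = preset_run
        sub = aln.subset_columns(list(range(0, aln.length, 16)))
        tree = RootedTree.from_newick(
            "(BRS:0.01,(wisent:0.02,(bison:0.01,yak:0.01):0.01):0.01);")
        sup = alrt_support(sub, tree, SubstitutionModel.jc())
        assert sup["bison+wisent+yak"] is None
        assert sup["bison+yak"] is not None


class TestHarmonicMean:
    def test_constant_samples(self):
        assert harmonic_mean_loglik([-12.5] * 20) == pytest.approx(-12.5)

    def test_hand_computed_two_samples(self):
        # harmonic mean of {1, 1/3} is 1/2
        got = harmonic_mean_loglik([0.0, math.log(1 / 3)])
        assert got == pytest.approx(math.log(0.5), abs=1e-12)

    def test_bayes_factor_identity(self):
        assert bayes_factor(-100.0, -100.0) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            harmonic_mean_loglik([])

    def test_trace_reader(self, tmp_path):
        p = tmp_path / "trace.txt"
        p.write_text("# burn-in removed\n-10.5\n-11.0 # draw 2\n\n-12.25\n")
        assert read_trace(p) == [-10.5, -11.0, -12.25]
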