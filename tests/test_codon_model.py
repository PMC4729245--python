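import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonsel.codon_model import (
    FitConfig,
    PruningEngine,
    ReversibleEig,
    SiteModelParams,
    _site_model_loglik,
    build_rate_matrix,
    empirical_codon_freqs,
    fit_branch_model,
    fit_site_model,
    likelihood_ratio_test,
    regroup_branch_test,
    unscaled_rate_matrix,
)
from codonsel.genetic_code import N_CODONS, SINGLE_STEP
from codonsel.seqio import CodonAlignment, LabeledTree
from codonsel.simulate import SimulationSpec, simulate_codon_alignment

FAST = FitConfig(n_starts=1)


def random_freqs(rng):
    f = rng.random(N_CODONS) + 0.05
    return f / f.sum()


class TestRateMatrix:
    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=10, deadline=None)
    def test_generator_properties(self, s):
        rng = np.random.default_rng(s)
        f = random_freqs(rng)
        kappa = float(rng.uniform(0.5, 5))
        omega = float(rng.uniform(0.02, 2))
        q = build_rate_matrix(kappa, omega, f)
        # rows sum to zero
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        # detailed balance pi_i q_ij = pi_j q_ji
        assert np.abs(f[:, None] * q - f[None, :] * q.T).max() < 1e-14
        # unit expected rate at stationarity
        assert -np.dot(f, np.diag(q)) == pytest.approx(1.0)
        # no multi-step rates
        assert np.all(q[~SINGLE_STEP & ~np.eye(61, dtype=bool)] == 0)

    def test_neutral_symmetric_case_has_equal_single_step_rates(self):
        f = np.full(N_CODONS, 1 / N_CODONS)
        q, _ = unscaled_rate_matrix(1.0, 1.0, f)
        rates = q[SINGLE_STEP]
        assert np.allclose(rates, rates[0])

    def test_invalid_parameters_rejected(self):
        f = np.full(N_CODONS, 1 / N_CODONS)
        with pytest.raises(ValueError):
            build_rate_matrix(-1.0, 0.5, f)
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, 0.5, np.ones(N_CODONS))

    @pytest.mark.parametrize("t", [1e-6, 0.01, 0.3, 2.0, 15.0])
    def test_transition_matrices_are_stochastic(self, t, rng):
        f = random_freqs(rng)
        eig = ReversibleEig(build_rate_matrix(2.0, 0.3, f), f)
        p = eig.pmat(t)
        assert np.all(p >= 0)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-10


class TestLikelihood:
    def _three_taxon(self, rng, n=5):
        labels = {"a": "social", "b": "subsocial", "c": "subsocial"}
        tree = LabeledTree.from_newick("(a:0.1,b:0.25,c:0.4);", labels)
        aln = CodonAlignment(["a", "b", "c"],
                             rng.integers(0, 61, (3, n)).astype(np.int16))
        return tree, aln

    def test_zero_branch_lengths_identical_seqs(self, rng):
        labels = {"a": "social", "b": "subsocial", "c": "subsocial"}
        tree = LabeledTree.from_newick("(a:0,b:0,c:0);", labels)
        row = rng.integers(0, 61, 20).astype(np.int16)
        aln = CodonAlignment(["a", "b", "c"], np.tile(row, (3, 1)))
        f = random_freqs(rng)
        eng = PruningEngine(tree, aln)
        eig = ReversibleEig(build_rate_matrix(2.0, 0.3, f), f)
        pm = {b: eig.pmat(0.0) for b in eng.branch_nodes}
        assert eng.loglik(pm, f) == pytest.approx(np.log(f[row]).sum())

    def test_saturation_limit_is_independence(self, rng):
        tree, aln = self._three_taxon(rng, n=30)
        f = random_freqs(rng)
        eng = PruningEngine(tree, aln)
        eig = ReversibleEig(build_rate_matrix(2.0, 0.3, f), f)
        pm = {b: eig.pmat(300.0) for b in eng.branch_nodes}
        expected = np.log(f[aln.codons.astype(np.int64)]).sum()
        assert eng.loglik(pm, f) == pytest.approx(expected, abs=1e-6)

    def test_pruning_matches_brute_force_enumeration(self, rng):
        tree, aln = self._three_taxon(rng)
        f = random_freqs(rng)
        eig = ReversibleEig(build_rate_matrix(1.8, 0.5, f), f)
        eng = PruningEngine(tree, aln)
        lens = {"a": 0.1, "b": 0.25, "c": 0.4}
        pm = {b: eig.pmat(lens[eng.nodes[b].name]) for b in eng.branch_nodes}
        ll = eng.loglik(pm, f)
        pa, pb, pc = (eig.pmat(lens[k]) for k in "abc")
        brute = sum(
            np.log(sum(f[x] * pa[x, sa] * pb[x, sb] * pc[x, sc]
                       for x in range(N_CODONS)))
            for sa, sb, sc in aln.codons.T
        )
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_rerooting_invariance(self, rng):
        # same unrooted 4-taxon tree rooted on two different branches
        labels = {"a": "social", "b": "subsocial", "c": "subsocial",
                  "d": "subsocial"}
        aln = CodonAlignment(list("abcd"),
                             rng.integers(0, 61, (4, 40)).astype(np.int16))
        f = random_freqs(rng)
        eig = ReversibleEig(build_rate_matrix(2.0, 0.2, f), f)
        lls = []
        for nwk in ["((a:0.1,b:0.2):0.05,(c:0.15,d:0.3):0.05);",
                    "(a:0.1,b:0.2,(c:0.15,d:0.3):0.1);",
                    "(c:0.15,d:0.3,(a:0.1,b:0.2):0.1);"]:
            tree = LabeledTree.from_newick(nwk, labels)
            eng = PruningEngine(tree, aln)
            lens = {"a": 0.1, "b": 0.2, "c": 0.15, "d": 0.3}
            pm = {}
            for b in eng.branch_nodes:
                name = eng.nodes[b].name
                pm[b] = eig.pmat(lens.get(name, 0.1))
            lls.append(eng.loglik(pm, f))
        assert lls[0] == pytest.approx(lls[1], abs=1e-8)
        assert lls[0] == pytest.approx(lls[2], abs=1e-8)

    def test_ambiguous_codons_marginalised(self, rng):
        tree, aln = self._three_taxon(rng, n=10)
        aln.codons[1, 3] = -1
        f = random_freqs(rng)
        eig = ReversibleEig(build_rate_matrix(2.0, 0.3, f), f)
        eng = PruningEngine(tree, aln)
        pm = {b: eig.pmat(0.2) for b in eng.branch_nodes}
        ll_missing = eng.loglik(pm, f)
        # marginal = sum over all states for the missing entry
        direct = 0.0
        col = aln.codons[:, 3].copy()
        for x in range(N_CODONS):
            one = aln.subset_columns(np.array([3]))
            one.codons[1, 0] = x
            e1 = PruningEngine(tree, one)
            direct += np.exp(e1.loglik({b: eig.pmat(0.2) for b in e1.branch_nodes}, f))
        rest = aln.subset_columns(np.array([i for i in range(10) if i != 3]))
        er = PruningEngine(tree, rest)
        ll_rest = er.loglik({b: eig.pmat(0.2) for b in er.branch_nodes}, f)
        assert ll_missing == pytest.approx(ll_rest + np.log(direct), abs=1e-8)


class TestBranchModelFits:
    def test_model_a_parameter_recovery(self, six_taxon_tree):
        # simulate 2000 codons under a single omega and refit
        tree, _ = six_taxon_tree
        true_omega = 0.15
        spec = SimulationSpec(tree=tree, kappa=2.0, n_codons=2000, seed=3,
                              omega_by_class={"internal": true_omega,
                                              "external_social": true_omega,
                                              "external_subsocial": true_omega})
        aln, _ = simulate_codon_alignment(spec)
        fit = fit_branch_model(tree, aln, "A", config=FAST)
        assert fit.converged
        assert fit.params.omega_by_class["all"] == pytest.approx(true_omega, abs=0.03)
        assert fit.log_likelihood < 0

    def test_model_d_on_two_taxa_equals_model_a(self, rng):
        labels = {"a": "social", "b": "subsocial"}
        tree = LabeledTree.from_newick("(a:0.1,b:0.1);", labels)
        spec = SimulationSpec(tree=tree, n_codons=300, seed=9,
                              omega_by_class={"internal": 0.2,
                                              "external_social": 0.2,
                                              "external_subsocial": 0.2})
        aln, _ = simulate_codon_alignment(spec)
        fa = fit_branch_model(tree, aln, "A", config=FAST)
        fd = fit_branch_model(tree, aln, "D", config=FAST)
        assert fd.log_likelihood == pytest.approx(fa.log_likelihood, abs=0.02)


class TestSiteModels:
    def test_m8_with_p0_one_is_m7(self, six_taxon_tree, rng):
        tree, _ = six_taxon_tree
        spec = SimulationSpec(tree=tree, n_codons=120, seed=2)
        aln, _ = simulate_codon_alignment(spec)
        eng = PruningEngine(tree, aln)
        freqs = empirical_codon_freqs(aln)
        lengths = np.full(len(eng.branch_nodes), 0.1)
        m7 = SiteModelParams("M7", 0.7, 1.9)
        m8 = SiteModelParams("M8", 0.7, 1.9, p0=1.0, omega_s=3.0)
        l7 = _site_model_loglik(eng, freqs, 2.0, m7, lengths)
        l8 = _site_model_loglik(eng, freqs, 2.0, m8, lengths)
        assert l7 == pytest.approx(l8, abs=1e-9)

    def test_category_weights_sum_to_one(self):
        for sp in (SiteModelParams("M7", 0.5, 2.0),
                   SiteModelParams("M8", 0.5, 2.0, p0=0.85, omega_s=2.5)):
            _, w = sp.categories()
            assert w.sum() == pytest.approx(1.0)

    def test_positive_selection_power_single_run(self, six_taxon_tree):
        # 10% of sites at omega = 3 on top of a purifying background:
        # M8 should beat M7 decisively. High-omega sites evolve faster in
        # total, so their tree is scaled by the relative rate of the
        # omega = 3 generator (mixture-consistent simulation).
        import re

        tree, labels = six_taxon_tree
        f = np.full(N_CODONS, 1 / N_CODONS)
        _, r_bg = unscaled_rate_matrix(2.0, 0.2, f)
        _, r_sel = unscaled_rate_matrix(2.0, 3.0, f)
        fac = r_sel / r_bg
        nwk_fast = re.sub(r":([0-9.]+)",
                          lambda m: ":%g" % (float(m.group(1)) * fac),
                          tree.to_newick())
        tree_fast = LabeledTree.from_newick(nwk_fast, labels)

        def omegas(w):
            return {"internal": w, "external_social": w, "external_subsocial": w}

        a1, _ = simulate_codon_alignment(
            SimulationSpec(tree=tree, n_codons=450, seed=21,
                           omega_by_class=omegas(0.2)))
        a2, _ = simulate_codon_alignment(
            SimulationSpec(tree=tree_fast, n_codons=50, seed=22,
                           omega_by_class=omegas(3.0)))
        aln = CodonAlignment(a1.taxa, np.hstack([a1.codons, a2.codons]))
        cfg = FitConfig(max_rounds=8)
        m7 = fit_site_model(tree, aln, "M7", config=cfg)
        m8 = fit_site_model(tree, aln, "M8", config=cfg,
                            init={"beta_p": m7.params.beta_p,
                                  "beta_q": m7.params.beta_q,
                                  "kappa": m7.details["kappa"],
                                  "p0": 0.9, "omega_s": 2.5,
                                  "lengths": np.array(list(m7.details["branch_lengths"].values()))})
        lrt = likelihood_ratio_test(m7, m8)
        assert lrt.df == 2
        assert lrt.p_value < 0.05
        assert m8.params.omega_s > 1.0


class TestLrt:
    def _fit_like(self, tag, lnl, nfree):
        from codonsel.codon_model import CodonModelFit

        return CodonModelFit(tag, None, lnl, nfree, True)

    def test_identical_fits_give_zero_and_p_one(self):
        r = likelihood_ratio_test(self._fit_like("A", -100.0, 20),
                                  self._fit_like("C", -100.0, 22))
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.df == 2

    def test_clamped_at_zero(self):
        r = likelihood_ratio_test(self._fit_like("A", -100.0, 20),
                                  self._fit_like("C", -100.001, 22))
        assert r.statistic == 0.0

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(self._fit_like("C", -100.0, 22),
                                  self._fit_like("B", -99.0, 21))

    def test_paper_style_df_bookkeeping(self):
        # A vs C adds 2 omegas; stat recovers chi2 p
        from scipy import stats as ss

        r = likelihood_ratio_test(self._fit_like("A", -9730.678, 20),
                                  self._fit_like("C", -9724.435, 22))
        assert r.statistic == pytest.approx(12.486, abs=0.01)
        assert r.p_value == pytest.approx(ss.chi2.sf(r.statistic, 2))
        assert r.p_value < 0.01


class TestRegroup:
    def test_regrouping_properties(self, six_taxon_tree):
        tree, _ = six_taxon_tree
        spec = SimulationSpec(tree=tree, n_codons=250, seed=5)
        aln, _ = simulate_codon_alignment(spec)
        fa = fit_branch_model(tree, aln, "A", config=FAST)
        rows = regroup_branch_test(tree, aln, "soc1",
                                   [[], ["sub3"], ["sub3", "sub4"]],
                                   config=FAST, fit_single=fa)
        # empty partner set falls back to mating-system classes
        assert set(rows[0]["omega"]) == {"internal", "external_social",
                                         "external_subsocial"}
        for r in rows:
            assert r["lnL"] >= fa.log_likelihood - 1e-6  # nesting monotonicity
            assert r["lrt_vs_single"].df == 2

    def test_unknown_focal_rejected(self, six_taxon_tree):
        tree, _ = six_taxon_tree
        spec = SimulationSpec(tree=tree, n_codons=60, seed=6)
        aln, _ = simulate_codon_alignment(spec)
        with pytest.raises(Exception, match="focal"):
            regroup_branch_test(tree, aln, "nope", [[]])
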