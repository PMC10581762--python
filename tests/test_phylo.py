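"""Phylogenetic comparative statistics: PGLS, ANOVA, ASR, MCC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from owlfield.phylo import (PagelLambdaGLS, Phylogeny, asr_bm, build_design,
                            lambda_transform, mcc_tree, pgls_fit, phylo_anova,
                            phylo_signal_lambda, phylostep)
from owlfield.simulate import simulate_yule


def bm_tips(tree, rng, lam=1.0, sigma2=1.0, mean=0.0):
    """Draw one lambda-BM tip vector on the height-normalised tree."""
    C, order = tree.vcv()
    Cn = C / np.diag(C).mean()
    L = np.linalg.cholesky(sigma2 * lambda_transform(Cn, lam)
                           + 1e-12 * np.eye(len(order)))
    return pd.Series(mean + L @ rng.standard_normal(len(order)), index=order)


class TestNewick:
    def test_shared_path_lengths(self):
        P = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        C, order = P.vcv()
        i, j = order.index("A"), order.index("B")
        assert C[i, j] == 1.0
        assert C[i, i] == 2.0
        assert C[order.index("C"), i] == 0.0

    def test_round_trip_random_trees(self):
        for seed in range(5):
            t = simulate_yule(12, 1.0, seed=seed)
            back = Phylogeny.from_newick(t.to_newick())
            C1, o1 = t.vcv()
            C2, o2 = back.vcv()
            assert o1 == o2
            assert np.allclose(C1, C2, atol=1e-9)

    def test_malformed_and_duplicates(self):
        with pytest.raises(ValueError):
            Phylogeny.from_newick("(A:1")
        with pytest.raises(ValueError):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")


class TestLambdaTransform:
    def test_endpoints_and_half(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.array_equal(lambda_transform(C, 1.0), C)
        assert np.array_equal(lambda_transform(C, 0.0), np.diag([2.0, 2.0]))
        assert lambda_transform(C, 0.5)[0, 1] == 0.5

    def test_psd_over_grid(self, balanced_tree):
        C, _ = balanced_tree.vcv()
        for lam in np.linspace(0, 1, 11):
            ev = np.linalg.eigvalsh(lambda_transform(C, lam))
            assert ev.min() >= -1e-8

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(2), 1.5)


class TestPGLS:
    def test_star_tree_equals_ols(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        y = 1.0 + X @ [2.0, -3.0] + rng.standard_normal(n)
        m = PagelLambdaGLS().fit(X, y, C=np.eye(n))
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(m.params_, ols.params, atol=1e-8)
        assert np.allclose(m.se_, ols.bse, atol=1e-8)
        assert np.allclose(m.pvalues_, ols.pvalues, atol=1e-8)

    def test_lambda_zero_equals_ols(self, rng):
        tree = simulate_yule(30, 1.0, seed=9)
        C, order = tree.vcv()
        X = rng.standard_normal((30, 1))
        y = pd.Series(0.5 + 1.5 * X[:, 0] + rng.standard_normal(30), index=order)
        m = PagelLambdaGLS(lam=0.0).fit(pd.DataFrame(X, index=order), y, tree=tree)
        # lambda = 0 whitens to a diagonal covariance with equal (ultrametric)
        # depths: identical to OLS
        ols = sm.OLS(y.to_numpy(), sm.add_constant(X)).fit()
        assert np.allclose(m.params_, ols.params, atol=1e-8)
        assert np.allclose(m.se_, ols.bse, atol=1e-8)

    def test_profile_beats_lambda_grid(self, rng):
        tree = simulate_yule(40, 1.0, seed=3)
        y = bm_tips(tree, rng, lam=0.6)
        m = PagelLambdaGLS().fit(None, y, tree=tree)
        for lam in np.linspace(0, 1, 101):
            mg = PagelLambdaGLS(lam=lam).fit(None, y, tree=tree)
            assert m.loglik_ >= mg.loglik_ - 1e-6

    def test_aic_bookkeeping(self, rng):
        tree = simulate_yule(25, 1.0, seed=4)
        y = bm_tips(tree, rng)
        m = PagelLambdaGLS().fit(None, y, tree=tree)
        assert m.aic_ == pytest.approx(-2 * m.loglik_ + 2 * (1 + 2))

    def test_singular_design_rejected(self, rng):
        tree = simulate_yule(20, 1.0, seed=5)
        y = bm_tips(tree, rng)
        X = np.ones((20, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="singular"):
            PagelLambdaGLS().fit(X, y.to_numpy(), tree=tree)

    def test_species_mismatch_rejected(self, rng):
        tree = simulate_yule(10, 1.0, seed=6)
        y = pd.Series(rng.standard_normal(10), index=[f"zz{i}" for i in range(10)])
        with pytest.raises(ValueError):
            PagelLambdaGLS().fit(None, y, tree=tree)


class TestSignal:
    def test_independent_noise_recovers_low_lambda(self):
        tree = simulate_yule(100, 1.0, seed=11)
        hits = 0
        reps = 100
        for s in range(reps):
            y = bm_tips(tree, np.random.default_rng(1000 + s), lam=0.0)
            if phylo_signal_lambda(y, tree).lambda_ < 0.1:
                hits += 1
        assert hits >= 0.9 * reps

    def test_brownian_motion_recovers_high_lambda(self):
        tree = simulate_yule(100, 1.0, seed=12)
        hits = 0
        reps = 100
        for s in range(reps):
            y = bm_tips(tree, np.random.default_rng(2000 + s), lam=1.0)
            if phylo_signal_lambda(y, tree).lambda_ > 0.8:
                hits += 1
        assert hits >= 0.9 * reps

    def test_constant_trait_degenerate(self):
        tree = simulate_yule(10, 1.0, seed=13)
        y = pd.Series(3.0, index=tree.tip_labels)
        assert phylo_signal_lambda(y, tree).degenerate


class TestPhylostep:
    def traits(self, tree, rng, diet_effect=0.0, noise=1.0):
        order = tree.tip_labels
        n = len(order)
        t = pd.DataFrame(index=pd.Index(order, name="species"))
        t["diet"] = rng.choice(["invertebrate", "vertebrate"], size=n)
        t["habitat"] = rng.choice(["dense", "semi-open", "open"], size=n)
        t["body_mass_g"] = rng.lognormal(6, 1, n)
        t["eye_axial_length_mm"] = rng.lognormal(3, 0.2, n)
        t["y"] = (diet_effect * (t["diet"] == "vertebrate")
                  + noise * rng.standard_normal(n))
        return t

    CANDS = ["diet", "habitat", "body_mass_g", "eye_axial_length_mm"]

    def test_huge_effect_selected(self, rng):
        tree = simulate_yule(23, 1.0, seed=21)
        t = self.traits(tree, rng, diet_effect=50.0, noise=1.0)
        res = phylostep(t, "y", self.CANDS, tree)
        assert "diet" in res.terms

    def test_null_prefers_intercept_only(self):
        # with pure-noise candidates the intercept-only model is the modal
        # outcome and every candidate's false-inclusion rate stays near the
        # small-sample AIC level (well below one half)
        from collections import Counter
        tree = simulate_yule(23, 1.0, seed=22)
        final = Counter()
        included = Counter()
        reps = 100
        for s in range(reps):
            t = self.traits(tree, np.random.default_rng(3000 + s))
            res = phylostep(t, "y", self.CANDS, tree)
            final[tuple(sorted(res.terms))] += 1
            for c in res.terms:
                included[c] += 1
        assert final.most_common(1)[0][0] == ()
        assert final[()] >= 2 * final.most_common(2)[1][1]
        assert all(included[c] <= 0.35 * reps for c in self.CANDS)

    def test_matches_exhaustive_enumeration(self):
        from itertools import combinations
        for s in (0, 1, 2):
            tree = simulate_yule(23, 1.0, seed=40 + s)
            t = self.traits(tree, np.random.default_rng(4000 + s),
                            diet_effect=6.0, noise=1.5)
            res = phylostep(t, "y", self.CANDS, tree)
            best = np.inf
            for k in range(5):
                for sub in combinations(self.CANDS, k):
                    X = build_design(t, list(sub)) if sub else None
                    m = pgls_fit(t["y"], X, tree=tree)
                    best = min(best, m.aic_)
            assert res.model.aic_ == pytest.approx(best, abs=1e-6)

    def test_trace_aic_decreases(self, rng):
        tree = simulate_yule(23, 1.0, seed=23)
        t = self.traits(tree, rng, diet_effect=8.0)
        res = phylostep(t, "y", self.CANDS, tree)
        acc = [tr["aic"] for tr in res.trace if tr["accepted"]]
        assert all(b < a + 1e-10 for a, b in zip(acc, acc[1:]))

    def test_collinear_candidate_flagged(self, rng):
        tree = simulate_yule(20, 1.0, seed=24)
        t = self.traits(tree, rng, diet_effect=0.0, noise=1.0)
        # a strong mass effect pulls mass in; its exact copy then makes the
        # add-move singular, which must be flagged and skipped
        t["y"] = 0.01 * t["body_mass_g"] + 0.5 * rng.standard_normal(len(t))
        t["mass_copy"] = t["body_mass_g"]
        res = phylostep(t, "y", ["body_mass_g", "mass_copy"], tree)
        assert res.terms in (["body_mass_g"], ["mass_copy"])
        assert res.collinear


class TestPhyloANOVA:
    def test_hand_computed_toy_F(self):
        tree = Phylogeny.from_newick(
            "((A:1,B:1,C:1):1,(D:1,E:1,F:1):1);")
        y = pd.Series([1, 2, 3, 4, 5, 6.0], index=list("ABCDEF"))
        g = pd.Series(["a"] * 3 + ["b"] * 3, index=list("ABCDEF"))
        res = phylo_anova(y, g, tree, n_sims=99, seed=0)
        assert res.F == pytest.approx(13.5, abs=1e-12)
        assert res.df_between == 1 and res.df_within == 4

    def test_constant_y_gives_zero_F(self):
        tree = simulate_yule(8, 1.0, seed=31)
        y = pd.Series(2.0, index=tree.tip_labels)
        g = pd.Series(["a", "b"] * 4, index=tree.tip_labels)
        assert phylo_anova(y, g, tree, n_sims=9, seed=0).F == 0.0

    def test_F_invariant_to_tree(self, rng):
        t1 = simulate_yule(12, 1.0, seed=32)
        t2 = simulate_yule(12, 1.0, seed=33)
        y = pd.Series(rng.standard_normal(12), index=t1.tip_labels)
        g = pd.Series(["a", "b", "c"] * 4, index=t1.tip_labels)
        r1 = phylo_anova(y, g, t1, n_sims=9, seed=0)
        r2 = phylo_anova(y, g, t2, n_sims=9, seed=0)
        assert r1.F == pytest.approx(r2.F, abs=1e-12)

    def test_p_resolution_and_determinism(self, rng):
        tree = simulate_yule(10, 1.0, seed=34)
        y = bm_tips(tree, rng)
        g = pd.Series(["a", "b"] * 5, index=tree.tip_labels)
        r1 = phylo_anova(y, g, tree, n_sims=199, seed=7)
        r2 = phylo_anova(y, g, tree, n_sims=199, seed=7)
        assert r1.p_sim == r2.p_sim
        assert round(r1.p_sim * 200) == pytest.approx(r1.p_sim * 200)

    def test_seed_required(self, rng):
        tree = simulate_yule(6, 1.0, seed=35)
        y = bm_tips(tree, rng)
        g = pd.Series(["a", "b"] * 3, index=tree.tip_labels)
        with pytest.raises(ValueError):
            phylo_anova(y, g, tree, n_sims=9)


class TestASR:
    def test_constant_tips(self):
        tree = simulate_yule(10, 1.0, seed=41)
        res = asr_bm(tree, pd.Series(4.2, index=tree.tip_labels))
        assert np.allclose(res.values.to_numpy(), 4.2)

    def test_two_tip_midpoint(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        res = asr_bm(tree, {"A": 0.0, "B": 10.0})
        assert res.values[res.root_label] == pytest.approx(5.0)

    def test_root_equals_gls_mean(self, rng):
        tree = simulate_yule(20, 1.0, seed=42)
        y = bm_tips(tree, rng, lam=1.0, mean=3.0)
        res = asr_bm(tree, y)
        C, order = tree.vcv()
        one = np.ones(len(order))
        w = np.linalg.solve(C, one)
        gls_mean = float(w @ y.reindex(order) / (w @ one))
        assert res.values[res.root_label] == pytest.approx(gls_mean, abs=1e-8)

    def test_reroot_invariance_along_edge(self):
        # same unrooted tree, rooted at two points of the same edge: the
        # shared clades keep their reconstructed states
        a = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        b = Phylogeny.from_newick("(((A:1,B:1):1,C:2):2,D:2);")
        tips = {"A": 1.0, "B": 5.0, "C": -2.0, "D": 3.0}
        ra, rb = asr_bm(a, tips), asr_bm(b, tips)
        byclade_a = {cl: ra.values[lab] for lab, cl in ra.clades.items()}
        byclade_b = {cl: rb.values[lab] for lab, cl in rb.clades.items()}
        ab = frozenset(["A", "B"])
        abc = frozenset(["A", "B", "C"])
        assert byclade_a[ab] == pytest.approx(byclade_b[ab], abs=1e-9)
        assert byclade_a[abc] == pytest.approx(byclade_b[abc], abs=1e-9)


class TestMCC:
    def test_single_tree_identity(self):
        t = simulate_yule(6, 1.0, seed=51)
        m = mcc_tree([t])
        C1, o1 = t.vcv()
        C2, o2 = m.vcv()
        assert o1 == o2 and np.allclose(C1, C2, atol=1e-9)

    def test_majority_topology_wins(self):
        base = simulate_yule(6, 1.0, seed=52)
        other = simulate_yule(6, 1.0, seed=53)
        sample = [Phylogeny.from_newick(base.to_newick()) for _ in range(9)]
        sample.append(other)
        m = mcc_tree(sample)
        want = {cl for cl, _ in _clade_sets(base)}
        got = {cl for cl, _ in _clade_sets(m)}
        assert got == want

    def test_heights_are_clade_means(self):
        t1 = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        t2 = Phylogeny.from_newick("((A:2,B:2):2,C:4);")
        m = mcc_tree([t1, t2])
        C, order = m.vcv()
        # root height mean of 2 and 4 = 3; cherry height mean of 1 and 2 = 1.5
        assert C[order.index("A"), order.index("A")] == pytest.approx(3.0)
        assert C[order.index("A"), order.index("B")] == pytest.approx(3.0 - 1.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mcc_tree([])


def _clade_sets(phy):
    from owlfield.phylo import _clades
    return _clades(phy.tree)
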