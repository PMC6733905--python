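"""Contrasts, phylogenetic signal, OU/BM regression, ancestral states,
phylogenetic PCA and disparity-through-time."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from climevol.comparative import (
    PhyloRegression,
    anc_states_bm,
    blomberg_k,
    bonferroni,
    contrasts_vs_age,
    dtt_envelope,
    lineage_trend,
    pgls_ou,
    phylo_cov,
    phylo_pca,
    phylosig_test,
    pic,
    resolve_polytomies,
)
from climevol.synthdata import sim_bd_tree, sim_trait
from climevol.treekit import parse_newick


class TestContrasts:
    def test_single_cherry_contrast(self):
        t = parse_newick("(A:1,B:1);")
        c = pic(t, {"A": 0.0, "B": 2.0})
        assert abs(c["contrast"].iloc[0]) == pytest.approx(2 / np.sqrt(2))
        assert c["age"].iloc[0] == pytest.approx(1.0)

    def test_constant_trait_zero_contrasts(self, five_tip_tree):
        c = pic(five_tip_tree, {l: 7.0 for l in five_tip_tree.tip_labels})
        assert np.allclose(c["contrast"], 0.0)

    def test_polytomy_raises_and_resolution_helps(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="polytom"):
            pic(t, {"A": 0.0, "B": 1.0, "C": 2.0})
        r = resolve_polytomies(t, seed=0)
        out = pic(r, {"A": 0.0, "B": 1.0, "C": 2.0})
        assert len(out) == 2

    def test_bm_contrasts_standardized_to_unit_variance(self):
        # under BM with rate s2, standardized contrasts ~ N(0, s2)
        tree = sim_bd_tree(1.0, 0.0, 16, seed=8)
        all_c = []
        for s in range(200):
            st_ = sim_trait(tree, sigma2=2.5, seed=s)
            all_c.extend(pic(tree, {l: st_[l] for l in tree.tip_labels})["contrast"])
        all_c = np.array(all_c)
        se = 2.5 * np.sqrt(2.0 / (len(all_c) - 1))
        assert abs(all_c.var(ddof=1) - 2.5) < 3 * se

    def test_contrasts_vs_age_flat_and_perfect(self):
        flat = pd.DataFrame({"contrast": [2.0, -2.0, 2.0, -2.0], "age": [1, 2, 3, 4]})
        slope, _, _ = contrasts_vs_age(flat)
        assert slope == pytest.approx(0.0)
        rising = pd.DataFrame({"contrast": [1.0, 2.0, 3.0], "age": [1, 2, 3]})
        slope, r, _ = contrasts_vs_age(rising)
        assert r == pytest.approx(1.0)

    def test_type_i_error_near_nominal_under_bm(self):
        tree = sim_bd_tree(1.0, 0.0, 20, seed=9)
        rej = 0
        reps = 500
        for s in range(reps):
            st_ = sim_trait(tree, sigma2=1.0, seed=10_000 + s)
            c = pic(tree, {l: st_[l] for l in tree.tip_labels})
            _, _, p = contrasts_vs_age(c)
            rej += p < 0.05
        assert abs(rej / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestBlombergK:
    def test_star_tree_k_equals_one_for_any_trait(self, star_tree_factory, rng):
        star = star_tree_factory(list("ABCDEFG"))
        for _ in range(3):
            y = dict(zip("ABCDEFG", rng.normal(size=7)))
            assert blomberg_k(star, y) == pytest.approx(1.0, abs=1e-10)

    def test_constant_trait_raises(self, five_tip_tree):
        with pytest.raises(ValueError):
            blomberg_k(five_tip_tree, {l: 1.0 for l in five_tip_tree.tip_labels})

    def test_permutation_p_bit_reproducible(self, five_tip_tree):
        y = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": 2.5}
        a = phylosig_test(five_tip_tree, y, n_perm=300, seed=11)
        b = phylosig_test(five_tip_tree, y, n_perm=300, seed=11)
        assert (a.K, a.P) == (b.K, b.P)
        assert a.P >= 1 / 301

    def test_bm_simulation_null_available(self, five_tip_tree):
        y = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": 2.5}
        res = phylosig_test(five_tip_tree, y, n_perm=200, seed=0, method="bm")
        assert 0 < res.P <= 1


class TestPhyloRegression:
    def test_star_tree_equals_ols(self, star_tree_factory, rng):
        labs = [f"s{i}" for i in range(15)]
        star = star_tree_factory(labs, depth=4.0)
        x = rng.normal(size=15)
        y = 0.5 + 1.8 * x + rng.normal(scale=0.4, size=15)
        fit = pgls_ou(star, pd.Series(y, index=labs), pd.DataFrame({"x": x}, index=labs))
        ols = stats.linregress(x, y)
        assert fit.params["x"] == pytest.approx(ols.slope, abs=1e-8)
        assert fit.params["const"] == pytest.approx(ols.intercept, abs=1e-8)

    def test_large_alpha_converges_to_ols(self, five_tip_tree):
        y = pd.Series({"A": 1.0, "B": 2.2, "C": 0.4, "D": 3.1, "E": 2.4})
        x = pd.DataFrame({"x": [0.1, 0.4, 0.0, 0.9, 0.8]}, index=list("ABCDE"))
        data = x.copy()
        data["y"] = y
        fit = PhyloRegression(five_tip_tree, data, "y", ["x"]).fit(alpha=50.0 / five_tip_tree.depth)
        ols = stats.linregress(x.loc[five_tip_tree.tip_labels, "x"], y.loc[five_tip_tree.tip_labels])
        assert fit.params["x"] == pytest.approx(ols.slope, abs=1e-4)

    def test_exact_linear_relation(self, five_tip_tree):
        x = pd.DataFrame({"x": [0.1, 0.4, 0.0, 0.9, 0.8]}, index=list("ABCDE"))
        y = 2.0 * x["x"]
        fit = pgls_ou(five_tip_tree, y, x)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_bm_model_equals_closed_form_gls(self, five_tip_tree):
        y = pd.Series({"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": 2.5})
        x = pd.DataFrame({"x": [0.1, 0.3, 0.2, 0.9, 0.7]}, index=list("ABCDE"))
        fit = pgls_ou(five_tip_tree, y, x, model="bm")
        order = five_tip_tree.tip_labels
        C = phylo_cov(five_tip_tree, order).to_numpy()
        Ci = np.linalg.inv(C)
        X = np.column_stack([np.ones(5), x.loc[order, "x"]])
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y.loc[order].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)
        assert fit.alpha == 0.0

    def test_polynomial_terms_and_bonferroni(self, star_tree_factory, rng):
        labs = [f"s{i}" for i in range(20)]
        star = star_tree_factory(labs)
        x = rng.normal(size=20)
        y = 1.0 + 0.5 * x - 0.8 * x**2 + rng.normal(scale=0.2, size=20)
        data = pd.DataFrame({"x": x, "y": y}, index=labs)
        fit = PhyloRegression(star, data, "y", ["x"], degree=2).fit()
        assert "x^2" in fit.params.index
        assert fit.params["x^2"] == pytest.approx(-0.8, abs=0.3)
        other = PhyloRegression(star, data, "y", ["x"]).fit()
        bonferroni([fit, other])
        assert (fit.pvalues_bonferroni >= fit.pvalues - 1e-15).all()
        assert (fit.pvalues_bonferroni <= 1.0).all()

    def test_missing_species_dropped_with_log(self, five_tip_tree, caplog):
        data = pd.DataFrame(
            {"x": [0.1, 0.2, 0.3, np.nan], "y": [1.0, 2.0, 1.5, 2.5]},
            index=list("ABCD"),
        )
        with caplog.at_level("INFO"):
            fit = PhyloRegression(five_tip_tree, data, "y", ["x"]).fit()
        assert fit.nobs == 3
        assert "dropped" in caplog.text

    def test_too_few_cases_raise(self, five_tip_tree):
        data = pd.DataFrame({"x": [0.1, 0.2], "y": [1.0, 2.0]}, index=list("AB"))
        with pytest.raises(ValueError):
            PhyloRegression(five_tip_tree, data, "y", ["x"])

    def test_aic_definition(self, star_tree_factory, rng):
        labs = [f"s{i}" for i in range(10)]
        star = star_tree_factory(labs)
        data = pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)}, index=labs)
        fit = PhyloRegression(star, data, "y", ["x"], model="bm").fit()
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.llf)  # 2 coefs + sigma2

    def test_summary_mentions_terms(self, star_tree_factory, rng):
        labs = [f"s{i}" for i in range(10)]
        star = star_tree_factory(labs)
        data = pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)}, index=labs)
        s = PhyloRegression(star, data, "y", ["x"]).fit().summary()
        assert "const" in s and "x" in s and "AIC" in s


class TestAncestralStates:
    def test_symmetric_cherry_root_midpoint(self):
        t = parse_newick("(A:1,B:1);")
        states = anc_states_bm(t, {"A": 0.0, "B": 2.0})
        assert states[t.root] == pytest.approx(1.0)

    def test_constant_trait_constant_states(self, five_tip_tree):
        states = anc_states_bm(five_tip_tree, {l: 3.3 for l in five_tip_tree.tip_labels})
        assert all(abs(v - 3.3) < 1e-10 for v in states.values())

    def test_matches_gls_closed_form(self, five_tip_tree):
        y = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": 2.5}
        states = anc_states_bm(five_tip_tree, y)
        order = five_tip_tree.tip_labels
        C = phylo_cov(five_tip_tree, order).to_numpy()
        Ci = np.linalg.inv(C)
        one = np.ones(5)
        yv = np.array([y[l] for l in order])
        a = one @ Ci @ yv / (one @ Ci @ one)
        depths = five_tip_tree.depths()
        # oracle: conditional mean with covariances = depth of mrca(node, tip)
        for node in five_tip_tree.internal_nodes():
            if node is five_tip_tree.root:
                assert states[node] == pytest.approx(a, abs=1e-10)
                continue
            below = {t.label for t in five_tip_tree.tips()}  # recompute per node

            def tipset(n):
                return {x.label for x in [n]} if n.is_leaf else {
                    lab for c in n.children for lab in tipset(c)
                }

            cvec = []
            for lab in order:
                anc = node
                while lab not in tipset(anc):
                    anc = anc.parent
                cvec.append(depths[anc])
            expect = a + np.array(cvec) @ Ci @ (yv - a)
            assert states[node] == pytest.approx(expect, abs=1e-10)

    def test_root_state_consistent_with_signal_machinery(self, five_tip_tree):
        # internal consistency: ancestral root equals the GLS grand mean
        y = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": 2.5}
        states = anc_states_bm(five_tip_tree, y)
        order = five_tip_tree.tip_labels
        Ci = np.linalg.inv(phylo_cov(five_tip_tree, order).to_numpy())
        one = np.ones(5)
        yv = np.array([y[l] for l in order])
        assert states[five_tip_tree.root] == pytest.approx(one @ Ci @ yv / (one @ Ci @ one))


class TestLineageTrend:
    def test_two_tip_hand_arithmetic(self):
        t = parse_newick("(A:2,B:2);")
        a, b = t.root.children
        states = {t.root: 0.0, a: 2.0, b: 6.0}
        out = lineage_trend(t, states, [0.0, 1.0, 2.0])
        assert np.allclose(out["mean_value"], 2.0)  # branch values 1 and 3

    def test_constant_states_flat_trend(self, five_tip_tree):
        states = {n: 4.0 for n in five_tip_tree.preorder()}
        out = lineage_trend(five_tip_tree, states, np.linspace(0, five_tip_tree.depth, 7))
        assert np.allclose(out["mean_value"], 4.0)

    def test_half_open_rule_at_speciation(self):
        # 3-tip tree; at the internal split both daughters count, parent does not
        t = parse_newick("((A:1,B:1):1,C:2);")
        inner = [n for n in t.internal_nodes() if n is not t.root][0]
        a, b = inner.children
        c = [x for x in t.root.children if x.is_leaf][0]
        states = {t.root: 0.0, inner: 4.0, a: 4.0, b: 4.0, c: 0.0}
        out = lineage_trend(t, states, [1.0])
        # crossing at t=1: daughters of inner (value 4) and branch to C (value 0)
        assert out["n_lineages"].iloc[0] == 3
        assert out["mean_value"].iloc[0] == pytest.approx((4.0 + 4.0 + 0.0) / 3)

    def test_time_outside_span_raises(self, five_tip_tree):
        states = {n: 1.0 for n in five_tip_tree.preorder()}
        with pytest.raises(ValueError):
            lineage_trend(five_tip_tree, states, [-0.5])
        with pytest.raises(ValueError):
            lineage_trend(five_tip_tree, states, [five_tip_tree.depth + 1.0])


class TestPhyloPCA:
    def test_star_tree_matches_ordinary_pca(self, star_tree_factory, rng):
        labs = [f"s{i}" for i in range(12)]
        star = star_tree_factory(labs)
        X = rng.normal(size=(12, 3))
        res = phylo_pca(star, pd.DataFrame(X, index=labs, columns=["a", "b", "c"]))
        Xc = X - X.mean(axis=0)
        ev, evec = np.linalg.eigh(Xc.T @ Xc / 11)
        ev, evec = ev[::-1], evec[:, ::-1]
        np.testing.assert_allclose(res.variance_fractions, ev / ev.sum(), atol=1e-8)
        for j in range(3):
            got = res.loadings.to_numpy()[:, j]
            assert np.allclose(got, evec[:, j], atol=1e-8) or np.allclose(got, -evec[:, j], atol=1e-8)

    def test_perfectly_correlated_variables_rank_one(self, star_tree_factory, rng):
        labs = [f"s{i}" for i in range(8)]
        star = star_tree_factory(labs)
        x = rng.normal(size=8)
        df = pd.DataFrame({"a": x, "b": 2 * x}, index=labs)
        res = phylo_pca(star, df)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self, five_tip_tree, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)), index=five_tip_tree.tip_labels,
                          columns=["a", "b", "c"])
        res = phylo_pca(five_tip_tree, df)
        V = res.loadings.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-10)


class TestDTT:
    def test_curve_starts_at_one(self, five_tip_tree):
        y = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": 2.5}
        res = dtt_envelope(five_tip_tree, y, n_sim=50, seed=0)
        assert res.observed[0] == pytest.approx(1.0)
        assert np.all(res.envelope_lo <= res.envelope_hi)
        assert res.heights[0] == 0.0

    def test_zero_disparity_raises(self, five_tip_tree):
        with pytest.raises(ValueError):
            dtt_envelope(five_tip_tree, {l: 1.0 for l in five_tip_tree.tip_labels}, n_sim=10)

    def test_white_noise_holds_disparity_near_present(self):
        # an unbalanced tree: phylogenetically structured trait loses subclade
        # disparity toward the present, white noise does not
        tree = sim_bd_tree(0.3, 0.0, 24, seed=31)
        depths = {lab: d for lab, d in
                  zip(tree.tip_labels, range(len(tree.tip_labels)))}
        rng = np.random.default_rng(0)
        structured = sim_trait(tree, sigma2=1.0, seed=3)
        y_struct = {l: structured[l] for l in tree.tip_labels}
        y_white = {l: float(v) for l, v in zip(tree.tip_labels, rng.normal(size=24))}
        r_struct = dtt_envelope(tree, y_struct, n_sim=20, seed=1)
        r_white = dtt_envelope(tree, y_white, n_sim=20, seed=1)
        # compare mean relative disparity over the most recent third of heights
        k = len(r_struct.heights) // 3
        assert r_white.observed[-k:].mean() > r_struct.observed[-k:].mean()

    def test_reproducible_per_seed(self, five_tip_tree):
        y = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": 2.5}
        a = dtt_envelope(five_tip_tree, y, n_sim=40, seed=5)
        b = dtt_envelope(five_tip_tree, y, n_sim=40, seed=5)
        np.testing.assert_array_equal(a.envelope_lo, b.envelope_lo)
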