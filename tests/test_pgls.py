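"""PGLS likelihood, lambda transform, ML and Bayesian fitting."""

import numpy as np
import pytest
from scipy import stats

from allocurve import pgls, synth, treeio
from allocurve.mcmc import McmcSettings, px
from allocurve.pgls import (
    RegressionDesign,
    build_design,
    deviation_code,
    deviation_effects,
    fit_pgls_bayes,
    fit_pgls_ml,
    gls_loglik,
    lambda_transform,
)


def _design(y, X, labels):
    names = [f"c{i}" for i in range(X.shape[1])]
    return RegressionDesign(y=y, X=X, names=names, labels=labels)


class TestGlsLoglik:
    def test_identity_covariance_is_ols_loglik(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=6)
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        d = _design(y, X, list("abcdef"))
        beta = np.array([0.3, 0.7])
        ll = gls_loglik(d, np.eye(6), beta, 1.3)
        ref = stats.norm.logpdf(y, X @ beta, np.sqrt(1.3)).sum()
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_brute_force_mvn_oracle_small_trees(self, random_trees):
        rng = np.random.default_rng(1)
        for tree in random_trees:
            if tree.n_tips > 12:
                continue
            V = treeio.vcv(tree)
            n = tree.n_tips
            y = rng.normal(size=n)
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            beta = rng.normal(size=2)
            s2 = float(rng.uniform(0.5, 2))
            d = _design(y, X, tree.tip_labels)
            ref = stats.multivariate_normal(mean=X @ beta, cov=s2 * V).logpdf(y)
            assert gls_loglik(d, V, beta, s2) == pytest.approx(ref, abs=1e-8)

    def test_sigma2_doubling_closed_form(self, three_tip_tree):
        V = treeio.vcv(three_tip_tree)
        y = np.array([1.0, 2.0, 3.0])
        d = _design(y, np.ones((3, 1)), three_tip_tree.tip_labels)
        beta = np.array([0.5])
        r = y - 0.5
        quad = r @ np.linalg.solve(V, r)
        s2 = 0.8
        delta = gls_loglik(d, V, beta, 2 * s2) - gls_loglik(d, V, beta, s2)
        assert delta == pytest.approx(-1.5 * np.log(2) + quad / (4 * s2), abs=1e-10)

    def test_sigma2_must_be_positive(self, three_tip_tree):
        d = _design(np.ones(3), np.ones((3, 1)), three_tip_tree.tip_labels)
        with pytest.raises(ValueError):
            gls_loglik(d, treeio.vcv(three_tip_tree), [0.0], 0.0)

    def test_singular_covariance_reported(self):
        d = _design(np.ones(2), np.ones((2, 1)), ["A", "B"])
        with pytest.raises(ValueError, match="singular|positive"):
            gls_loglik(d, np.ones((2, 2)), [0.0], 1.0)


class TestLambdaTransform:
    def test_endpoints_and_half(self, three_tip_tree):
        V = treeio.vcv(three_tip_tree)
        assert np.allclose(lambda_transform(V, 1.0), V)
        assert np.allclose(lambda_transform(V, 0.0), np.diag(np.diag(V)))
        half = lambda_transform(V, 0.5)
        a, b = (three_tip_tree.tip_labels.index(x) for x in "AB")
        assert half[a, b] == pytest.approx(0.5)
        assert np.allclose(np.diag(half), np.diag(V))

    def test_out_of_range(self, three_tip_tree):
        with pytest.raises(ValueError):
            lambda_transform(treeio.vcv(three_tip_tree), 1.2)


class TestDeviationCoding:
    def test_three_groups(self):
        cols, groups = deviation_code(["g1", "g2", "g3", "g3"])
        assert groups == ["g1", "g2", "g3"]
        assert np.allclose(cols[0], [1, 0])
        assert np.allclose(cols[1], [0, 1])
        assert np.allclose(cols[2], [-1, -1])

    def test_two_groups(self):
        cols, _ = deviation_code(["a", "b", "a"])
        assert set(np.unique(cols)) == {-1.0, 1.0}

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            deviation_code(["a", "a"])

    def test_fitted_group_effects_sum_to_zero(self, small_dataset):
        sp = small_dataset.species.copy()
        sub = synth.assign_subclades(small_dataset.tree, 3, min_size=8)
        sp["subclade"] = sp.species.map(sub)
        design = build_design(sp, "subclade_curve")
        V = treeio.vcv(small_dataset.tree)
        fit = fit_pgls_ml(design, V, lam=1.0)
        dev = [n for n in design.names if n.startswith("dev_int[")]
        effects = deviation_effects(
            fit.coef.loc[dev, "estimate"].to_numpy(), design.groups
        )
        assert effects.sum() == pytest.approx(0.0, abs=1e-8)


class TestFitPglsMl:
    def test_lambda_zero_equals_ols(self, small_dataset):
        design = build_design(small_dataset.species, "global_curve")
        V = treeio.vcv(small_dataset.tree)
        fit = fit_pgls_ml(design, V, lam=0.0)
        ols = np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        assert np.allclose(fit.coef.estimate.to_numpy(), ols, atol=1e-8)

    def test_brownian_recovery_and_permutation(self):
        """On Brownian-simulated regressions the ML lambda is high and the
        slope is recovered; permuting tip labels destroys the signal."""
        hits_lam = hits_ci = perm_low = 0
        n_rep = 100
        n_perm = 50
        tree = synth.simulate_tree(200, seed=123)
        V = treeio.vcv(tree)
        n = tree.n_tips
        tq = stats.t.ppf(0.975, n - 2)
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            L = np.linalg.cholesky(V / tree.depth())
            x = 1.5 + L @ rng.normal(size=n) * 1.5
            resid = L @ rng.normal(size=n) * 0.25
            y = -0.4 + 0.6 * x + resid
            d = _design(y, np.column_stack([np.ones(n), x]), tree.tip_labels)
            fit = fit_pgls_ml(d, V)
            est = fit.coef.loc["c1"]
            if fit.lambda_hat >= 0.9:
                hits_lam += 1
            if abs(est.estimate - 0.6) <= tq * est.se:
                hits_ci += 1
            if rep < n_perm:
                perm = rng.permutation(n)
                dp = _design(y[perm], d.X[perm], tree.tip_labels)
                if fit_pgls_ml(dp, V).lambda_hat <= 0.1:
                    perm_low += 1
        assert hits_lam >= 0.9 * n_rep
        assert hits_ci >= 0.9 * n_rep
        assert perm_low >= 0.9 * n_perm

    def test_needs_enough_rows(self):
        d = _design(np.ones(3), np.column_stack([np.ones(3), np.arange(3.0)]),
                    list("abc"))
        with pytest.raises(ValueError):
            fit_pgls_ml(d, np.eye(3))


class TestFitPglsBayes:
    def test_prior_recovery_without_likelihood(self):
        d = _design(
            np.zeros(3),
            np.column_stack([np.ones(3), np.arange(3.0)]),
            list("abc"),
        )
        chain = fit_pgls_bayes(
            d, np.eye(3),
            settings=McmcSettings(iterations=40_000, burnin=2_000, thin=4, seed=1),
            likelihood_off=True,
        )
        sds = chain.beta.std(axis=0)
        assert np.all(np.abs(sds - 2.5) / 2.5 < 0.05)

    def test_star_tree_matches_ols(self, small_dataset):
        design = build_design(small_dataset.species, "global_curve")
        chain = fit_pgls_bayes(
            design, np.eye(design.n),
            settings=McmcSettings(iterations=30_000, burnin=5_000, thin=10, seed=2),
        )
        ols = np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        med = np.median(chain.beta, axis=0)
        sd = chain.beta.std(axis=0)
        assert np.all(np.abs(med - ols) < 2 * sd)

    def test_summary_structure(self, small_dataset):
        design = build_design(small_dataset.species, "global_curve")
        V = treeio.vcv(small_dataset.tree)
        chain = fit_pgls_bayes(
            design, V,
            settings=McmcSettings(iterations=20_000, burnin=4_000, thin=16, seed=3),
        )
        s = chain.summary()
        assert {"median", "mean", "l95", "u95", "px", "rhat"} <= set(s.columns)
        assert (s.l95 <= s["median"]).all() and (s["median"] <= s.u95).all()
        assert chain.beta.shape[0] == chain.settings.n_samples


class TestPx:
    @pytest.mark.parametrize(
        "samples,expected",
        [
            ([-1.0, 1.0, 1.0, 1.0], 0.25),
            ([0.5, 1.0, 2.0], 0.0),
            (np.concatenate([np.linspace(-1, -0.01, 50), np.linspace(0.01, 1, 50)]), 0.5),
        ],
    )
    def test_values(self, samples, expected):
        assert px(samples) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            px([])

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.normal(rng.normal(), 1.0, size=101)
            assert 0.0 <= px(s) <= 0.5


class TestBuildDesign:
    def test_unknown_model(self, small_dataset):
        with pytest.raises(ValueError):
            build_design(small_dataset.species, "cubic")

    def test_group_columns_present(self, small_dataset):
        sp = small_dataset.species.copy()
        sub = synth.assign_subclades(small_dataset.tree, 4, min_size=8)
        sp["subclade"] = sp.species.map(sub)
        d = build_design(sp, "subclade_curve")
        k = sp.subclade.nunique()
        assert k >= 3
        assert sum(n.startswith("dev_body2[") for n in d.names) == k - 1
        assert d.X.shape[1] == 3 + 3 * (k - 1)
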