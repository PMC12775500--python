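"""Hierarchical phylogenetic mixed models on individual-level data."""

import numpy as np
import pandas as pd
import pytest

from allocurve import dataprep, pglmm, synth, treeio
from allocurve.mcmc import McmcSettings
from allocurve.pglmm import (
    HierarchicalSpec,
    fit_global_curve_with_species_variation,
    fit_hierarchical,
    fit_hierarchical_within_quadratic,
    fit_pglmm,
    heritability,
)

FAST = McmcSettings(iterations=2500, burnin=600, thin=2, seed=3)


def make_centred(cfg):
    ds = synth.simulate_micro_macro(cfg)
    return ds, dataprep.within_group_center(ds.individuals)


@pytest.fixture(scope="module")
def curved_data():
    """s1 < 0 dataset with species-level variance, shared by fit tests."""
    cfg = synth.MicroMacroConfig(
        n_species=120, n_individuals=15, species_resid_sd=0.1, seed=21
    )
    return make_centred(cfg)


class TestHeritability:
    def test_arithmetic(self):
        assert heritability(1.0, 1.0, 2.0) == pytest.approx(0.25)

    def test_zero_phylo(self):
        assert heritability(0.0, 1.0, 1.0) == 0.0

    def test_pure_phylo(self):
        assert heritability(2.0, 0.0, 0.0) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0, 0.0)

    def test_vectorized_with_slope_inclusion(self):
        h = heritability(np.array([1.0, 2.0]), 1.0, 1.0, sigma2_slope=1.0)
        assert np.allclose(h, [0.25, 0.4])


class TestSpecValidation:
    def test_unknown_role(self):
        with pytest.raises(ValueError):
            HierarchicalSpec(fixed=("intercept", "cubic"), random=())

    def test_slope_and_within_quadratic_exclusive(self):
        with pytest.raises(ValueError):
            HierarchicalSpec(
                fixed=("intercept", "within_body_sq_centred"),
                random=("species_slope",),
            )


class TestDegenerateInputs:
    def test_species_missing_from_tree(self, curved_data):
        ds, centred = curved_data
        bad = centred.copy()
        bad.loc[bad.index[:5], "species"] = "not_a_tip"
        with pytest.raises(ValueError, match="not found in tree"):
            fit_pglmm(pglmm.GLOBAL_CURVE_SPEC, bad, ds.tree, FAST)

    def test_single_species_across_terms_inestimable(self):
        cfg = synth.MicroMacroConfig(n_species=2, n_individuals=8, seed=1)
        ds, centred = make_centred(cfg)
        only = centred[centred.species == centred.species.iloc[0]]
        with pytest.raises(ValueError, match="single species"):
            fit_pglmm(pglmm.HIERARCHICAL_SPEC, only, ds.tree, FAST)

    def test_within_effects_need_replication(self, curved_data):
        ds, centred = curved_data
        trimmed = centred.groupby("species").head(1)
        with pytest.raises(ValueError, match=">= 2 individuals"):
            fit_pglmm(pglmm.HIERARCHICAL_SPEC, trimmed, ds.tree, FAST)


class TestVarianceRecovery:
    def test_null_variances_shrink_to_zero(self):
        """With no phylogenetic or species-level noise the corresponding
        variance components must collapse relative to the residual."""
        cfg = synth.MicroMacroConfig(
            n_species=150, n_individuals=10,
            sigma2_resid=0.0, species_resid_sd=0.0, slope_noise_sd=0.0,
            seed=17,
        )
        ds, centred = make_centred(cfg)
        fit = fit_pglmm(
            pglmm.GLOBAL_CURVE_SPEC, centred, ds.tree,
            McmcSettings(iterations=3000, burnin=800, thin=2, seed=5),
        )
        med = fit.variance_samples.median()
        assert med["sigma2_phylo"] < 0.1 * med["sigma2_residual"]
        assert med["sigma2_species"] < 0.1 * med["sigma2_residual"]

    def test_variance_samples_nonnegative_and_h_bounded(self, curved_data):
        ds, centred = curved_data
        fit = fit_global_curve_with_species_variation(centred, ds.tree, FAST)
        assert (fit.variance_samples.to_numpy() >= 0).all()
        assert np.all((fit.heritability_samples >= 0) & (fit.heritability_samples <= 1))

    def test_slope_variance_identified(self):
        """sigma2_slope separates heterogeneous from homogeneous
        within-species slopes."""
        base = dict(n_species=100, n_individuals=15, seed=31)
        het_cfg = synth.MicroMacroConfig(slope_noise_sd=0.2, **base)
        hom_cfg = synth.MicroMacroConfig(slope_noise_sd=0.0, s1=0.0, **base)
        ds_het, cen_het = make_centred(het_cfg)
        ds_hom, cen_hom = make_centred(hom_cfg)
        f_het = fit_hierarchical(cen_het, ds_het.tree, FAST)
        f_hom = fit_hierarchical(cen_hom, ds_hom.tree, FAST)
        v_het = f_het.variance_samples["sigma2_slope"]
        v_hom = f_hom.variance_samples["sigma2_slope"]
        assert v_het.median() > 10 * v_hom.median()
        assert v_het.quantile(0.025) > 0.2**2 / 4  # clearly excludes zero


class TestParameterRecovery:
    def test_within_and_across_slopes_recovered(self):
        """Distinct within- (0.4) and across-species (0.6) slopes are both
        recovered by the hierarchical model."""
        rng = np.random.default_rng(77)
        tree = synth.simulate_tree(150, seed=77)
        x = synth.simulate_body_bm(tree, 0.0225, 1.5, rng=rng)
        ybar = 0.1 + 0.6 * x + rng.normal(0, 0.1, tree.n_tips)
        rows = []
        for i, s in enumerate(tree.tip_labels):
            w = rng.normal(0, 0.2, 12)
            w -= w.mean()
            eps = rng.normal(0, 0.05, 12)
            eps -= eps.mean()
            for j in range(12):
                rows.append((s, x[i] + w[j], ybar[i] + 0.4 * w[j] + eps[j]))
        df = pd.DataFrame(rows, columns=["species", "log10_body_g", "log10_brain_g"])
        centred = dataprep.within_group_center(df)
        spec = HierarchicalSpec(
            fixed=("intercept", "across_body", "within_body"),
            random=("phylogenetic", "species_identity", "species_slope"),
        )
        fit = fit_pglmm(
            spec, centred, tree,
            McmcSettings(iterations=3000, burnin=800, thin=2, seed=9),
        )
        means = {
            n: fit.fixed_samples[:, i].mean()
            for i, n in enumerate(fit.fixed_names)
        }
        assert means["within_body"] == pytest.approx(0.4, abs=0.05)
        assert means["across_body"] == pytest.approx(0.6, abs=0.05)


class TestStructuralBehaviour:
    def test_pooled_quadratic_significant_on_curved_data(self, curved_data):
        ds, centred = curved_data
        fit = fit_global_curve_with_species_variation(centred, ds.tree, FAST)
        b2 = fit.fixed_samples[:, fit.fixed_names.index("body2")]
        assert np.median(b2) < 0
        assert fit.fixed_px("body2") < 0.05

    def test_species_slope_deviations_track_size_bias(self, curved_data):
        """Posterior species slopes decline with species body size when
        the generating slope law has s1 < 0."""
        ds, centred = curved_data
        fit = fit_hierarchical(centred, ds.tree, FAST)
        dev = fit.species_slope_deviation
        body = ds.species.set_index("species").log10_body_g
        corr = np.corrcoef(dev.to_numpy(), body.loc[dev.index].to_numpy())[0, 1]
        assert corr < -0.3

    def test_within_quadratic_isolates_slope_gradient(self, curved_data):
        """The species-centred within-quadratic term recovers s1/2, the
        size gradient of within-species slopes."""
        ds, centred = curved_data
        fit = fit_hierarchical_within_quadratic(centred, ds.tree, FAST)
        w2 = fit.fixed_samples[:, fit.fixed_names.index("within_body_sq_centred")]
        s1_half = ds.config.s1 / 2.0
        assert np.median(w2) == pytest.approx(s1_half, abs=0.02)
        assert fit.fixed_px("within_body_sq_centred") < 0.05

    def test_shared_terms_agree_in_homogeneous_slope_limit(self):
        """With homogeneous within-species slopes (s1 = 0, no slope noise)
        the two hierarchical parameterizations estimate the same average
        within-species slope."""
        cfg = synth.MicroMacroConfig(
            n_species=100, n_individuals=15, s1=0.0, slope_noise_sd=0.0,
            species_resid_sd=0.1, seed=41,
        )
        ds, centred = make_centred(cfg)
        fh = fit_hierarchical(centred, ds.tree, FAST)
        fq = fit_hierarchical_within_quadratic(centred, ds.tree, FAST)
        wh = fh.fixed_samples[:, fh.fixed_names.index("within_body")]
        wq = fq.fixed_samples[:, fq.fixed_names.index("within_body")]
        assert abs(np.median(wh) - np.median(wq)) < 0.05
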