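"""Mixed-model association: GRM, REML, Wald tests, genomic control."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from euradmix import simdata
from euradmix.assoc import (
    GRM,
    compute_grm,
    fit_lmm,
    genomic_control_lambda,
    nested_adjustment_scan,
)
from euradmix.assoc import test_snp as wald_snp_test


@pytest.fixture(scope="module")
def founder_gset():
    panel = simdata.draw_ancestral_frequencies(3000, np.array([[0.0]]), seed=801)
    gset, _ = simdata.simulate_admixed_cohort(panel, 150, np.ones((150, 1)), 1, seed=802)
    return gset


class TestGrm:
    def test_duplicate_individuals_related(self, founder_gset):
        dup = founder_gset.take_samples(np.r_[0, 0, np.arange(1, 50)])
        K = compute_grm(dup).matrix
        assert K[0, 1] == pytest.approx(K[0, 0], rel=0.01)

    def test_unrelated_off_diagonals_small(self, founder_gset):
        K = compute_grm(founder_gset).matrix
        off = K[np.triu_indices_from(K, k=1)]
        # off-diagonals are ~N(0, 1/S): check scale, not the extreme order stat
        assert np.quantile(np.abs(off), 0.99) < 3 / np.sqrt(founder_gset.n_variants)
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.05)

    def test_single_snp_outer_product(self, founder_gset):
        one = founder_gset.take_variants(np.array([0]))
        g = one.genotypes[:, 0].astype(float)
        p = g.mean() / 2
        x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        assert np.allclose(compute_grm(one).matrix, np.outer(x, x))

    def test_monomorphic_rejected(self, founder_gset):
        import pandas as pd

        from euradmix.genio import GenotypeSet

        G = founder_gset.genotypes.copy()
        G[:, 0] = 0
        gm = GenotypeSet(G, founder_gset.variants, founder_gset.samples)
        with pytest.raises(ValueError):
            compute_grm(gm)


class TestFitLmm:
    def test_reduces_to_ols_when_no_genetic_variance(self, founder_gset):
        rng = np.random.default_rng(803)
        n = founder_gset.n_samples
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)  # no polygenic component
        grm = compute_grm(founder_gset)
        fit = fit_lmm(y, X, grm)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.beta, ols.params, atol=1e-6)
        assert fit.sigma_g2 == pytest.approx(0.0, abs=1e-4)

    def test_heritability_recovered(self):
        # h2 = 0.5 simulation: REML estimate within its sampling band
        panel = simdata.draw_ancestral_frequencies(5000, np.array([[0.0]]), seed=804)
        gset, _ = simdata.simulate_admixed_cohort(panel, 500, np.ones((500, 1)), 1, seed=805)
        grm = compute_grm(gset)
        rng = np.random.default_rng(806)
        vals, vecs = grm.eig()
        u = vecs @ (rng.normal(size=500) * np.sqrt(vals * 0.5))
        y = 1.0 + u + rng.normal(0, np.sqrt(0.5), 500)
        fit = fit_lmm(y, np.ones((500, 1)), grm)
        assert 0.35 <= fit.h2 <= 0.65

    def test_intercept_equivariance(self, founder_gset):
        rng = np.random.default_rng(807)
        n = founder_gset.n_samples
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        grm = compute_grm(founder_gset)
        f1 = fit_lmm(y, X, grm)
        f2 = fit_lmm(y + 10.0, X, grm)
        assert f2.beta[0] == pytest.approx(f1.beta[0] + 10.0, abs=1e-6)
        assert f2.beta[1] == pytest.approx(f1.beta[1], abs=1e-6)

    def test_rank_deficient_rejected(self, founder_gset):
        n = founder_gset.n_samples
        X = np.ones((n, 2))
        with pytest.raises(ValueError):
            fit_lmm(np.zeros(n), X, None)

    def test_wald_close_to_lrt(self, founder_gset):
        rng = np.random.default_rng(808)
        n = founder_gset.n_samples
        g = founder_gset.genotypes[:, 5].astype(float)
        y = 0.3 * g + rng.normal(size=n)
        res = wald_snp_test(y, None, None, g)
        x0 = np.ones((n, 1))
        x1 = np.column_stack([x0, g])
        ll0 = fit_lmm(y, x0, None).loglik_ml
        ll1 = fit_lmm(y, x1, None).loglik_ml
        p_lrt = stats.chi2.sf(2 * (ll1 - ll0), df=1)
        assert abs(np.log10(res.p) - np.log10(p_lrt)) < 0.3


class TestGenomicControl:
    def test_uniform_p_lambda_one(self):
        rng = np.random.default_rng(809)
        lam = genomic_control_lambda(rng.uniform(size=10_000))
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            genomic_control_lambda(np.r_[np.zeros(1), np.full(200, 0.5)])


@pytest.fixture(scope="module")
def confounded_cohort():
    """Three-way gradient cohort with focal SNP and ancestry-only trait."""
    from conftest import PAIRWISE_FST

    panel = simdata.draw_ancestral_frequencies(2000, PAIRWISE_FST, seed=810)
    panel = simdata.plant_differentiated_snp(panel, np.array([0.931, 0.029, 0.029]))
    gset, truth = simdata.simulate_admixed_cohort(
        panel, 500, simdata.gradient_alpha_sampler(), 50, seed=811
    )
    return panel, gset, truth


class TestSnpTest:
    def test_confounded_unadjusted_false_positive(self, confounded_cohort):
        panel, gset, truth = confounded_cohort
        tab = simdata.simulate_trait(truth, gset, 2.0, 0.0, 1.0, seed=812)
        j = panel.focal_index
        res = wald_snp_test(tab.values, None, None, gset.genotypes[:, j])
        assert res.p < 1e-4  # ancestry confounding masquerades as association

    def test_collinear_snp_reported_not_crash(self, confounded_cohort):
        _, gset, truth = confounded_cohort
        y = np.random.default_rng(813).normal(size=gset.n_samples)
        cov = gset.genotypes[:, 0].astype(float)
        res = wald_snp_test(y, cov, None, gset.genotypes[:, 0])
        assert np.isnan(res.beta)
        assert res.p == 1.0


class TestNestedLadder:
    def test_identical_pc_sets_identical_aic(self, confounded_cohort):
        panel, gset, truth = confounded_cohort
        from euradmix import structure

        tab = simdata.simulate_trait(truth, gset, 2.0, 0.0, 1.0, seed=814)
        grm = compute_grm(gset, exclude=[panel.focal_index])
        pcs = structure.pca_fit(gset, n_axes=4).scores
        j = panel.focal_index
        local = truth.alpha[:, 0] * 2
        out = nested_adjustment_scan(
            tab.values, grm, pcs, pcs, local, gset.genotypes[:, j]
        )
        ref = out[out.adjustment == "GRM+Ref_PCs"].aic.iloc[0]
        pop = out[out.adjustment == "GRM+Pop_PCs"].aic.iloc[0]
        assert ref == pytest.approx(pop, abs=1e-8)
        assert out.attrs["delta_aic_ref_vs_pop"] == pytest.approx(0.0, abs=1e-8)

    def test_confounded_null_attenuates_down_ladder(self, confounded_cohort):
        panel, gset, truth = confounded_cohort
        from euradmix import localanc, structure

        tab = simdata.simulate_trait(truth, gset, 2.0, 0.0, 1.0, seed=815)
        j = panel.focal_index
        grm = compute_grm(gset, exclude=[j])
        pcs = structure.pca_fit(gset, n_axes=4).scores
        lap = localanc.infer_local_ancestry(
            gset.haplotypes,
            np.vstack([panel.freqs[0], 0.5 * (panel.freqs[1] + panel.freqs[2])]),
            panel.map_cM, panel.chrom, G=50,
            prior_alpha=np.column_stack([truth.alpha[:, 0], 1 - truth.alpha[:, 0]]),
        )
        out = nested_adjustment_scan(
            tab.values, grm, pcs, pcs, lap.dosage[:, j], gset.genotypes[:, j]
        )
        betas = out.set_index("adjustment").beta
        assert abs(betas["GRM+Ref_PCs"]) < abs(betas["unadjusted"])
        assert out.set_index("adjustment").p["unadjusted"] < 1e-4
        assert out.set_index("adjustment").p["GRM+Ref_PCs+Local_Anc"] > 0.01

    def test_genuine_effect_stable_across_ladder(self, confounded_cohort):
        panel, gset, truth = confounded_cohort
        from euradmix import structure

        tab = simdata.simulate_trait(truth, gset, 0.0, 0.4, 1.0, seed=816)
        j = panel.focal_index
        grm = compute_grm(gset, exclude=[j])
        pcs = structure.pca_fit(gset, n_axes=4).scores
        local = truth.alpha[:, 0] * 2
        out = nested_adjustment_scan(
            tab.values, grm, pcs, pcs, local, gset.genotypes[:, j]
        )
        t = out.set_index("adjustment")
        for rung in ("GRM", "GRM+Ref_PCs", "GRM+Pop_PCs"):
            assert abs(t.beta[rung] - t.beta["unadjusted"]) < 2 * t.se[rung]
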