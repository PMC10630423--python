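"""Generative-model checks: drift calibration, tracts, traits, meiosis."""

import numpy as np
import pytest

from euradmix import popstats, simdata
from euradmix.simdata import (
    draw_ancestral_frequencies,
    plant_differentiated_snp,
    simulate_admixed_cohort,
    simulate_offspring,
    simulate_trait,
    solve_cluster_drifts,
)


class TestAncestralFrequencies:
    def test_zero_drift_copies_ancestral(self):
        panel = draw_ancestral_frequencies(
            500, np.zeros((3, 3)), seed=1
        )
        assert np.allclose(panel.freqs[0], panel.freqs[1])
        assert np.allclose(panel.freqs[0], panel.freqs[2])

    def test_beta_variance_matches_balding_nichols(self):
        # Var(p_k) = F p (1-p): p=0.5, F=0.5 -> 0.125, checked against
        # brute-force Beta sampling through the panel constructor
        reps = 10_000
        panel = draw_ancestral_frequencies(
            reps, np.array([[0.0, 0.5], [0.5, 0.0]]), freq_range=(0.499, 0.501), seed=2
        )
        var = panel.freqs[0].var()
        assert var == pytest.approx(0.125, rel=0.05)

    def test_pairwise_fst_recovered(self):
        panel = draw_ancestral_frequencies(
            100_000, np.array([[0.0, 0.033], [0.033, 0.0]]), seed=3
        )
        fst = popstats.hudson_fst(panel.freqs[0], panel.freqs[1])
        assert fst == pytest.approx(0.033, abs=0.002)

    def test_three_way_drift_solution_exact(self):
        d = np.array([[0, 0.033, 0.032], [0.033, 0, 0.028], [0.032, 0.028, 0]])
        F = solve_cluster_drifts(d)
        assert np.allclose(F, [0.037, 0.029, 0.027])

    def test_rejects_asymmetric_drift(self):
        with pytest.raises(ValueError):
            draw_ancestral_frequencies(10, np.array([[0, 0.1], [0.2, 0]]), seed=0)

    def test_seeded_runs_bit_reproducible(self):
        a = draw_ancestral_frequencies(200, np.array([[0, 0.1], [0.1, 0]]), seed=7)
        b = draw_ancestral_frequencies(200, np.array([[0, 0.1], [0.1, 0]]), seed=7)
        assert np.array_equal(a.freqs, b.freqs)


class TestCohortSimulation:
    def test_pure_ancestry_gives_single_tract_label(self, small_panel):
        alpha = np.tile([1.0, 0.0], (30, 1))
        gset, truth = simulate_admixed_cohort(small_panel, 30, alpha, 10, seed=5)
        assert (truth.tracts == 0).all()
        # genotype frequencies match cluster-0 frequencies
        emp = gset.allele_frequencies()
        resid = emp - small_panel.freqs[0]
        assert abs(resid.mean()) < 0.01

    @pytest.mark.parametrize("G", [10, 50, 100])
    def test_tract_length_exponential(self, G):
        # mean tract length for ancestry k is 1/(G (1-alpha_k)) Morgans
        panel = draw_ancestral_frequencies(
            4000, np.array([[0, 0.1], [0.1, 0]]), seed=G, n_chrom=1, chrom_cm=400.0
        )
        alpha = np.tile([0.5, 0.5], (60, 1))
        _, truth = simulate_admixed_cohort(panel, 60, alpha, G, seed=G + 1)
        spacing_m = 0.1 / 100.0  # marker spacing in Morgans
        lengths = []
        for row in truth.tracts:
            switch = np.flatnonzero(np.diff(row) != 0)
            if switch.size >= 2:
                lengths.extend(np.diff(switch) * spacing_m)  # interior tracts only
        expected = 1.0 / (G * 0.5)
        assert np.mean(lengths) == pytest.approx(expected, rel=0.10)

    def test_allele_frequency_is_alpha_mixture(self, small_panel):
        rng = np.random.default_rng(8)
        alpha = rng.dirichlet([1, 1], 400)
        gset, truth = simulate_admixed_cohort(small_panel, 400, alpha, 20, seed=9)
        expected = truth.alpha.mean(axis=0) @ small_panel.freqs
        resid = gset.allele_frequencies() - expected
        assert abs(resid.mean()) < 0.005
        assert np.abs(resid).mean() < 0.03

    def test_random_mating_fit_centered_at_zero(self, three_way_panel):
        gset, _ = simulate_admixed_cohort(
            three_way_panel, 400, simdata.gradient_alpha_sampler(), 50,
            assortment_r=0.0, seed=10,
        )
        fit = popstats.per_snp_fit(gset)
        assert abs(np.nanmean(fit)) < 0.003

    def test_rejects_off_simplex_alpha(self, small_panel):
        bad = np.tile([0.6, 0.6], (5, 1))
        with pytest.raises(ValueError):
            simulate_admixed_cohort(small_panel, 5, bad, 10, seed=0)


class TestFocalSnp:
    def test_inserted_frequencies_exact(self, three_way_panel):
        freqs = np.array([0.931, 0.029, 0.029])
        panel = plant_differentiated_snp(three_way_panel, freqs)
        j = panel.focal_index
        assert np.allclose(panel.freqs[:, j], freqs)
        assert panel.freqs[0, j] - panel.freqs[1, j] == pytest.approx(0.902)

    def test_deterministic_allele_given_tract(self, three_way_panel):
        panel = plant_differentiated_snp(three_way_panel, np.array([1.0, 0.0, 0.0]))
        j = panel.focal_index
        gset, truth = simulate_admixed_cohort(
            panel, 50, np.tile([1 / 3, 1 / 3, 1 / 3], (50, 1)), 30, seed=11
        )
        tract_count = (truth.tracts[0::2, j] == 0).astype(int) + (
            truth.tracts[1::2, j] == 0
        ).astype(int)
        assert np.array_equal(gset.genotypes[:, j], tract_count)

    def test_position_outside_map_rejected(self, three_way_panel):
        with pytest.raises(ValueError):
            plant_differentiated_snp(
                three_way_panel, np.array([0.5, 0.5, 0.5]), map_position=("1", 5000.0)
            )


class TestTrait:
    def test_pure_noise_centered(self, admixed_cohort):
        gset, truth = admixed_cohort
        tab = simulate_trait(truth, gset, 0.0, 0.0, 1.0, seed=12)
        assert abs(tab.values.mean()) < 3.0 / np.sqrt(len(tab.values))
        assert tab.values.std() == pytest.approx(1.0, rel=0.2)

    def test_ancestry_slope_recovered_by_ols(self, admixed_cohort):
        gset, truth = admixed_cohort
        tab = simulate_trait(truth, gset, 2.0, 0.0, 1.0, seed=13)
        x = truth.alpha[:, 0]
        slope = np.polyfit(x, tab.values, 1)[0]
        se = 1.0 / (np.std(x) * np.sqrt(len(x)))
        assert slope == pytest.approx(2.0, abs=3 * se)

    def test_focal_required_for_snp_effect(self, admixed_cohort):
        gset, truth = admixed_cohort
        with pytest.raises(ValueError):
            simulate_trait(truth, gset, 0.0, 0.5, 1.0, seed=14)


class TestOffspring:
    def test_offspring_haplotypes_are_parental_recombinants(self, small_panel):
        parents, _ = simulate_admixed_cohort(
            small_panel, 4, np.tile([0.5, 0.5], (4, 1)), 10, seed=15
        )
        off = simulate_offspring(parents, [(0, 1), (2, 3)], seed=16)
        # each offspring allele must match one of its parent's two haplotypes
        for o, (pa, pb) in enumerate([(0, 1), (2, 3)]):
            h = off.haplotypes[2 * o]
            ok = (h == parents.haplotypes[2 * pa]) | (h == parents.haplotypes[2 * pa + 1])
            assert ok.all()

    def test_unphased_parents_rejected(self, small_panel):
        parents, _ = simulate_admixed_cohort(
            small_panel, 2, np.tile([0.5, 0.5], (2, 1)), 10, seed=17
        )
        from euradmix.genio import GenotypeSet

        unphased = GenotypeSet(
            parents.genotypes, parents.variants, parents.samples
        )
        with pytest.raises(ValueError):
            simulate_offspring(unphased, [(0, 1)], seed=18)
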