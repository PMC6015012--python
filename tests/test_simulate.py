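import numpy as np
import pytest
from scipy import stats

from sigleak.core import GenomicInterval
from sigleak.features import features_for_interval
from sigleak.simulate import (
    CohortLayout,
    SimulationConfig,
    expand_by_resampling,
    simulate_cohort,
    simulate_genotypes,
    simulate_hic,
    simulate_profile,
)


class TestGenotypeSimulation:
    def test_hardy_weinberg_frequencies_at_p02(self):
        config = SimulationConfig(n_individuals=10_000, n_variants=1, seed=4)
        layout = CohortLayout.from_config(config)
        layout.allele_freqs[:] = 0.2
        gm = simulate_genotypes(config, layout)
        counts = [(gm.genotypes[0] == g).sum() for g in (0, 1, 2)]
        expected = np.array([0.04, 0.32, 0.64]) * 10_000
        assert stats.chisquare(counts, expected).pvalue > 1e-3

    def test_degenerate_allele_frequencies(self):
        config = SimulationConfig(n_individuals=50, n_variants=3, seed=4)
        layout = CohortLayout.from_config(config)
        layout.allele_freqs[:] = 1e-12  # p -> 0: everyone keeps both copies
        assert (simulate_genotypes(config, layout).genotypes == 2).all()
        layout.allele_freqs[:] = 1.0  # p = 1: everyone homozygous deleted
        assert (simulate_genotypes(config, layout).genotypes == 0).all()

    def test_reproducible_and_seed_sensitive(self):
        config = SimulationConfig(n_individuals=8, n_variants=40, seed=11)
        a = simulate_genotypes(config)
        b = simulate_genotypes(config)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        c = simulate_genotypes(SimulationConfig(n_individuals=8, n_variants=40, seed=12))
        assert (a.genotypes != c.genotypes).any()


class TestProfileSimulation:
    @pytest.fixture
    def noiseless(self):
        config = SimulationConfig(
            n_individuals=2, n_variants=30, min_len=4, noise="none",
            baseline_depth=10.0, low_depth_fraction=0.0, repeat_fraction=0.0, seed=2,
        )
        return config, CohortLayout.from_config(config)

    def test_homozygous_deletion_interior_exactly_zero(self, noiseless):
        config, layout = noiseless
        profile = simulate_profile(np.zeros(30, dtype=int), config, layout)
        for iv in layout.panel:
            assert (profile.slice(iv) == 0).all()

    def test_no_deletion_gives_baseline_everywhere_in_exons(self, noiseless):
        config, layout = noiseless
        profile = simulate_profile(np.full(30, 2, dtype=int), config, layout)
        for v, iv in enumerate(layout.panel):
            lo, hi = layout.region_bounds[v]
            exon = GenomicInterval(config.chrom, lo, hi)
            assert (profile.slice(exon) == 10.0).all()

    def test_heterozygous_half_dip_and_rho(self, noiseless):
        config, layout = noiseless
        profile = simulate_profile(np.ones(30, dtype=int), config, layout)
        mapp = layout.mappability()
        iv = layout.panel[0]
        assert (profile.slice(iv) == 5.0).all()
        r = features_for_interval(profile, mapp, iv)
        assert r.rho == pytest.approx(0.5)

    def test_profiles_reproducible_per_individual(self):
        config = SimulationConfig(n_individuals=3, n_variants=20, seed=5)
        truth, cohort_a, _ = simulate_cohort(config)
        _, cohort_b, _ = simulate_cohort(config)
        for ind in cohort_a.individuals:
            np.testing.assert_array_equal(
                cohort_a.pooled(ind).values, cohort_b.pooled(ind).values
            )
        assert (
            cohort_a.pooled("ind0000").values != cohort_a.pooled("ind0001").values
        ).any()

    def test_layout_encodes_depth_mixture_and_repeats(self):
        config = SimulationConfig(n_individuals=2, n_variants=400, seed=6)
        layout = CohortLayout.from_config(config)
        assert set(np.unique(layout.depths)) == {config.low_depth, config.baseline_depth}
        assert 0 < layout.repeat_mask.sum() < 400
        mapp = layout.mappability()
        v = int(np.flatnonzero(layout.repeat_mask)[0])
        lo, hi = layout.region_bounds[v]
        assert (mapp.values[lo - 1 : hi] == config.repeat_mappability).all()
        assert mapp.values[0] == 1.0

    def test_negative_binomial_noise_overdisperses(self):
        base = SimulationConfig(n_individuals=1, n_variants=200, noise="poisson",
                                low_depth_fraction=0.0, seed=8)
        layout = CohortLayout.from_config(base)
        g2 = np.full(200, 2, dtype=int)
        pois = simulate_profile(g2, base, layout)
        nb_cfg = SimulationConfig(n_individuals=1, n_variants=200, noise="nb",
                                  nb_dispersion=2.0, low_depth_fraction=0.0, seed=8)
        nb = simulate_profile(g2, nb_cfg, layout)
        exonic = pois.values > 0
        assert nb.values[nb.values > 0].var() > 2 * pois.values[exonic].var()


class TestHicSimulation:
    @pytest.fixture
    def hic_setup(self):
        config = SimulationConfig.hi_c(noise="none", n_variants=30, seed=13)
        return config, CohortLayout.from_config(config)

    def test_matrix_symmetric(self):
        config = SimulationConfig.hi_c(n_variants=20, seed=13)  # Poisson noise
        layout = CohortLayout.from_config(config)
        m = simulate_hic(config, np.full(20, 2, dtype=int), layout)
        np.testing.assert_array_equal(m, m.T)
        assert m.min() >= 0

    def test_homozygous_deletion_bins_have_zero_marginal(self, hic_setup):
        config, layout = hic_setup
        genotypes = np.full(30, 2, dtype=int)
        genotypes[4] = 0
        m = simulate_hic(config, genotypes, layout)
        iv = layout.panel[4]
        bins = range((iv.start - 1) // config.hic_bin_size,
                      (iv.end - 1) // config.hic_bin_size + 1)
        colsums = m.sum(axis=0)
        for b in bins:
            assert colsums[b] == 0.0

    def test_background_marginal_matches_harmonic_closed_form(self, hic_setup):
        config, layout = hic_setup
        m = simulate_hic(config, np.full(30, 2, dtype=int), layout)
        n = m.shape[0]
        harmonic = np.cumsum(1.0 / np.arange(1, n + 1))
        i = np.arange(n)
        expected = config.hic_depth * (harmonic[i] + harmonic[n - 1 - i] - 1.0)
        np.testing.assert_allclose(m.sum(axis=0), expected, rtol=1e-12)


class TestResampling:
    def test_degenerate_variant_stays_degenerate(self):
        config = SimulationConfig(n_individuals=6, n_variants=4, seed=3)
        layout = CohortLayout.from_config(config)
        layout.allele_freqs[:] = 1e-12
        gm = simulate_genotypes(config, layout)
        expanded = expand_by_resampling(gm, 50, seed=1)
        assert (expanded.genotypes == 2).all()
        assert expanded.n_individuals == 50

    def test_empty_output(self):
        gm = simulate_genotypes(SimulationConfig(n_individuals=4, n_variants=3, seed=3))
        assert expand_by_resampling(gm, 0, seed=1).n_individuals == 0

    def test_resampled_frequencies_within_three_standard_errors(self):
        config = SimulationConfig(n_individuals=40, n_variants=5, seed=19)
        gm = simulate_genotypes(config)
        expanded = expand_by_resampling(gm, 10_000, seed=7)
        for v in range(5):
            target = gm.freqs[v]
            got = expanded.freqs[v]
            se = np.sqrt(target * (1 - target) / 10_000)
            assert (np.abs(got - target) <= 3 * se + 1e-12).all()
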