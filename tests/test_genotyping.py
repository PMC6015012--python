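import numpy as np
import pytest

from helpers import brute_force_column_sums
from sigleak.core import DeletionPanel, GenomicInterval, SignalProfile
from sigleak.genotyping import (
    GenotypingParams,
    genotype_large_deletions,
    genotype_small_deletions,
    hic_to_profile,
    make_denovo_windows,
)
from sigleak.simulate import SimulationConfig, simulate_cohort


def _candidate_profile():
    """Three length-5 candidates with controlled features.

    A: mappable, rho 0.1;  B: repeat-like (m_bar 2.0), rho 0.05;
    C: mappable, rho 0.3.  All have tau 22.5 and eta 0.8.
    """
    signal = np.full(130, 9.0)
    mapp = np.ones(130)
    panel = []
    for k, (name, rho, m) in enumerate([("A", 0.1, 1.0), ("B", 0.05, 2.0), ("C", 0.3, 1.0)]):
        base = 40 * k
        signal[base + 15 : base + 20] = 25.0  # left flank mean
        signal[base + 25 : base + 30] = 20.0  # right flank mean
        signal[base + 20 : base + 25] = rho * (25.0 + 20.0) / 2.0
        mapp[base + 15 : base + 30] = m
        panel.append(GenomicInterval("chr1", base + 21, base + 25, id=name))
    return (
        SignalProfile("chr1", signal),
        SignalProfile("chr1", mapp),
        DeletionPanel(panel),
    )


class TestSmallDeletionGenotyping:
    def test_default_parameter_set(self):
        params = GenotypingParams()
        assert (params.m_max, params.tau_min, params.eta_min) == (1.5, 10.0, 0.5)

    def test_filters_and_rho_ranking(self):
        profile, mapp, panel = _candidate_profile()
        calls = genotype_small_deletions(profile, mapp, panel, GenotypingParams(n_top=1))
        assert [c.interval.id for c in calls] == ["A"]  # B fails m_max, C ranks below
        assert calls[0].call == 0 and calls[0].rank == 1
        assert calls[0].score == pytest.approx(0.1)

    def test_survivors_sorted_ascending_rho(self):
        profile, mapp, panel = _candidate_profile()
        calls = genotype_small_deletions(profile, mapp, panel, GenotypingParams(n_top=3))
        assert [c.interval.id for c in calls] == ["A", "C"]

    def test_all_filtered_gives_empty_list(self):
        profile, mapp, panel = _candidate_profile()
        strict = GenotypingParams(m_max=0.5, n_top=1)
        assert genotype_small_deletions(profile, mapp, panel, strict) == []

    def test_undefined_features_fail_filters(self):
        profile, mapp, panel = _candidate_profile()
        profile.values[15:20] = 0.0  # A's left flank -> eta UNDEFINED
        calls = genotype_small_deletions(profile, mapp, panel, GenotypingParams(n_top=3))
        assert [c.interval.id for c in calls] == ["C"]

    def test_deterministic_with_coordinate_tie_break(self):
        profile, mapp, panel = _candidate_profile()
        profile.values[20:25] = 0.0
        profile.values[100:105] = 0.0  # A and C tie at rho 0
        first = genotype_small_deletions(profile, mapp, panel, GenotypingParams(n_top=2))
        second = genotype_small_deletions(profile, mapp, panel, GenotypingParams(n_top=2))
        assert [c.interval.id for c in first] == ["A", "C"]  # genomic order on ties
        assert [(c.interval.id, c.rank, c.score) for c in first] == [
            (c.interval.id, c.rank, c.score) for c in second
        ]

    def test_loosening_filters_never_removes_survivors(self):
        config = SimulationConfig(n_individuals=4, n_variants=80, seed=3)
        truth, cohort, mapp = simulate_cohort(config)
        profile = cohort.pooled(cohort.individuals[0])
        strict = genotype_small_deletions(
            profile, mapp, truth.panel, GenotypingParams(1.5, 10.0, 0.5, n_top=80)
        )
        loose = genotype_small_deletions(
            profile, mapp, truth.panel, GenotypingParams(3.0, 2.0, 0.1, n_top=80)
        )
        assert {c.interval.id for c in strict} <= {c.interval.id for c in loose}

    def test_noiseless_recovery_of_homozygous_deletions(self):
        config = SimulationConfig(
            n_individuals=3, n_variants=120, min_len=3, noise="none",
            repeat_fraction=0.0, low_depth_fraction=0.0, seed=9,
        )
        truth, cohort, mapp = simulate_cohort(config)
        for k, ind in enumerate(cohort.individuals):
            genotypes = truth.genotypes.genotypes[:, k]
            true_homo = {
                truth.panel[v].id for v in range(len(genotypes)) if genotypes[v] == 0
            }
            calls = genotype_small_deletions(
                cohort.pooled(ind), mapp, truth.panel,
                GenotypingParams(n_top=max(1, len(true_homo))),
            )
            assert {c.interval.id for c in calls} == true_homo  # precision = recall = 1


class TestLargeDeletionGenotyping:
    def test_lowest_signal_called_first(self):
        profile = SignalProfile("chr1", np.r_[np.zeros(10), np.full(10, 8.0)])
        mapp = SignalProfile("chr1", np.ones(20))
        panel = DeletionPanel(
            [GenomicInterval("chr1", 1, 10, id="zero"), GenomicInterval("chr1", 11, 20, id="high")]
        )
        calls = genotype_large_deletions(profile, mapp, panel, n_top=1)
        assert [c.interval.id for c in calls] == ["zero"]
        assert calls[0].score == 0.0

    def test_mappability_filter_trumps_signal(self):
        profile = SignalProfile("chr1", np.r_[np.zeros(10), np.full(10, 8.0)])
        mapp = SignalProfile("chr1", np.r_[np.full(10, 2.0), np.ones(10)])
        panel = DeletionPanel(
            [GenomicInterval("chr1", 1, 10, id="zero"), GenomicInterval("chr1", 11, 20, id="high")]
        )
        calls = genotype_large_deletions(profile, mapp, panel, m_max=1.5, n_top=2)
        assert [c.interval.id for c in calls] == ["high"]

    def test_n_top_equal_to_panel_calls_everything(self):
        profile = SignalProfile("chr1", np.arange(30, dtype=float))
        mapp = SignalProfile("chr1", np.ones(30))
        panel = DeletionPanel(
            [GenomicInterval("chr1", 1 + 10 * k, 10 * (k + 1), id=f"w{k}") for k in range(3)]
        )
        calls = genotype_large_deletions(profile, mapp, panel, n_top=3)
        assert len(calls) == 3


class TestDenovoWindows:
    def test_exon_tiling_drops_partial_window(self):
        exon = GenomicInterval("chr1", 1, 12)
        panel = make_denovo_windows("small", exonic_regions=[exon])
        assert [(iv.start, iv.end) for iv in panel] == [(1, 5), (6, 10)]
        assert panel.source == "denovo_small"

    def test_genome_wide_1kb_tiling(self):
        panel = make_denovo_windows("large", chrom_lengths={"chr1": 2500})
        assert [(iv.start, iv.end) for iv in panel] == [(1, 1000), (1001, 2000)]
        assert panel.source == "denovo_large"

    def test_short_exon_yields_no_windows(self):
        panel = make_denovo_windows(
            "small", exonic_regions=[GenomicInterval("chr1", 1, 4), GenomicInterval("chr1", 10, 16)]
        )
        assert [(iv.start, iv.end) for iv in panel] == [(10, 14)]

    def test_small_mode_requires_exons(self):
        with pytest.raises(ValueError):
            make_denovo_windows("small")
        with pytest.raises(ValueError):
            make_denovo_windows("medium", chrom_lengths={"chr1": 100})


class TestHicToProfile:
    def test_column_sums_by_hand(self):
        profile = hic_to_profile(np.array([[1, 2], [2, 3]]), bin_size=10)
        np.testing.assert_array_equal(profile.values, [3, 5])
        assert profile.resolution == 10

    def test_zero_and_diagonal_matrices(self):
        np.testing.assert_array_equal(
            hic_to_profile(np.zeros((3, 3)), 1).values, np.zeros(3)
        )
        d = np.array([4.0, 5.0, 6.0])
        np.testing.assert_array_equal(hic_to_profile(np.diag(d), 1).values, d)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            hic_to_profile(np.ones((2, 3)), 1)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(5):
            m = rng.integers(0, 50, size=(50, 50)).astype(float)
            got = hic_to_profile(m, 1000).values
            np.testing.assert_array_equal(got, brute_force_column_sums(m))

    def test_symmetric_matrix_column_sums_equal_row_sums(self, rng):
        m = rng.integers(0, 20, size=(30, 30)).astype(float)
        m = m + m.T
        np.testing.assert_array_equal(m.sum(axis=0), m.sum(axis=1))
        np.testing.assert_array_equal(hic_to_profile(m, 1).values, m.sum(axis=1))
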