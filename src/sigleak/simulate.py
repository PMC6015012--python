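"""Synthetic cohorts with the statistical structure the linking attack assumes.

The generator emulates, at desk scale, the data regimes the attack targets:

* Hardy-Weinberg deletion genotypes over a shared variant panel, one
  deletion-allele frequency per variant;
* read-depth signal profiles where the expected signal inside a deletion is
  ``baseline x (intact copies / 2)`` — a homozygous deletion is a clean dip
  to zero, a heterozygous one a half-depth dip — with Poisson (or
  negative-binomial) counting noise;
* an RNA-seq-like regime (deep, narrow: exon blocks separated by
  zero-signal introns, small 1-10 bp deletions centered in exons) and a
  ChIP-seq-like regime (broad, shallow: coverage everywhere, 1000-5000 bp
  deletions);
* a multi-mappability track with repeat-like high-signal stretches over a
  fraction of variants, which the genotyping filters must reject;
* Hi-C contact matrices with a distance-decay background whose marginals
  dip over deletion bins;
* genotype-dataset expansion by per-variant resampling from empirical
  genotype frequencies.

Everything is driven by one integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (
    Cohort,
    DeletionPanel,
    GenomicInterval,
    GenotypeMatrix,
    MappabilityProfile,
    SignalProfile,
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the RNA-seq-like small-deletion regime: 50 individuals,
    500 deletions of 1-10 bp centered in 100 bp exons separated by 100 bp
    introns, Poisson depth 30, deletion-allele frequencies U(0.1, 0.5),
    20% of variants in low-depth (12x) regions, and 5% of variants inside
    repeat-like stretches with multi-mappability 3.0.
    """

    n_individuals: int = 50
    n_variants: int = 500
    mode: str = "small"  # "small" (exonic) or "large" (broad coverage)
    min_len: int = 1
    max_len: int = 10
    af_min: float = 0.1
    af_max: float = 0.5
    baseline_depth: float = 30.0
    low_depth_fraction: float = 0.2
    low_depth: float = 12.0
    noise: str = "poisson"  # "poisson" | "nb" | "none"
    nb_dispersion: float = 0.1
    repeat_fraction: float = 0.05
    repeat_mappability: float = 3.0
    exon_length: int = 100
    intron_length: int = 100
    chrom: str = "chr1"
    # Hi-C regime
    hic_bin_size: int = 1000
    hic_depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("small", "large"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if not (0 < self.af_min <= self.af_max < 1):
            raise ValueError("allele frequencies must satisfy 0 < af_min <= af_max < 1")
        if self.baseline_depth <= 0 or self.low_depth <= 0:
            raise ValueError("depths must be positive")
        if self.noise not in ("poisson", "nb", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.mode == "small" and self.exon_length < 4 * self.max_len:
            raise ValueError("exons must be at least 4x the longest deletion")

    @classmethod
    def chip_seq_large(cls, **overrides) -> "SimulationConfig":
        """Broad/shallow regime for large deletions (pooled ChIP-seq-like)."""
        base = dict(
            mode="large",
            n_variants=100,
            min_len=1000,
            max_len=5000,
            baseline_depth=5.0,
            low_depth=2.0,
            low_depth_fraction=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def hi_c(cls, **overrides) -> "SimulationConfig":
        """Large deletions spanning multiple Hi-C bins.

        The panel holds 100 deletions so a typical individual carries ~10
        homozygous ones — enough distinct zero-marginal bins to identify
        each of the 20 individuals uniquely.
        """
        base = dict(
            mode="large",
            n_individuals=20,
            n_variants=100,
            min_len=2000,
            max_len=4000,
            low_depth_fraction=0.0,
        )
        base.update(overrides)
        return cls(**base)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


@dataclass
class CohortLayout:
    """Deterministic genome layout shared by every individual of a cohort:
    the variant panel, per-variant allele frequencies and region depths,
    the repeat mask, and the mappability track."""

    config: SimulationConfig
    panel: DeletionPanel
    allele_freqs: np.ndarray  # (n_variants,)
    depths: np.ndarray  # (n_variants,) expected depth of the variant's region
    repeat_mask: np.ndarray  # (n_variants,) bool
    chrom_length: int
    region_bounds: List[Tuple[int, int]]  # covered region per variant (1-based)

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "CohortLayout":
        rng = _rng(config, 0)
        n = config.n_variants
        lengths = rng.integers(config.min_len, config.max_len + 1, size=n)
        freqs = rng.uniform(config.af_min, config.af_max, size=n)
        depths = np.where(
            rng.random(n) < config.low_depth_fraction,
            config.low_depth,
            config.baseline_depth,
        )
        repeats = rng.random(n) < config.repeat_fraction

        intervals: List[GenomicInterval] = []
        bounds: List[Tuple[int, int]] = []
        if config.mode == "small":
            unit = config.intron_length + config.exon_length
            for v in range(n):
                exon_start = v * unit + config.intron_length + 1
                exon_end = exon_start + config.exon_length - 1
                start = exon_start + (config.exon_length - int(lengths[v])) // 2
                intervals.append(
                    GenomicInterval(
                        config.chrom, start, start + int(lengths[v]) - 1, id=f"del{v:05d}"
                    )
                )
                bounds.append((exon_start, exon_end))
            chrom_length = n * unit + config.intron_length
        else:
            unit = 4 * config.max_len
            for v in range(n):
                block_start = v * unit + 1
                block_end = (v + 1) * unit
                start = block_start + config.max_len
                intervals.append(
                    GenomicInterval(
                        config.chrom, start, start + int(lengths[v]) - 1, id=f"del{v:05d}"
                    )
                )
                bounds.append((block_start, block_end))
            chrom_length = n * unit + config.max_len

        panel = DeletionPanel(intervals, source="known_panel")
        return cls(config, panel, freqs, depths, repeats, chrom_length, bounds)

    def mappability(self) -> MappabilityProfile:
        values = np.ones(self.chrom_length)
        for v, iv in enumerate(self.panel):
            if self.repeat_mask[v]:
                lo, hi = self.region_bounds[v]
                values[lo - 1 : hi] = self.config.repeat_mappability
        return MappabilityProfile(self.config.chrom, values)


@dataclass
class TruthSet:
    panel: DeletionPanel
    genotypes: GenotypeMatrix
    identity: Dict[str, str]  # signal-profile id -> genotype-dataset id
    layout: CohortLayout


def simulate_genotypes(
    config: SimulationConfig, layout: Optional[CohortLayout] = None
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: with deletion-allele frequency p, intact
    copies are 0/1/2 with probabilities p^2, 2p(1-p), (1-p)^2; independent
    across variants and individuals."""
    if layout is None:
        layout = CohortLayout.from_config(config)
    rng = _rng(config, 1)
    p = layout.allele_freqs[:, None]
    cdf0 = p**2
    cdf1 = cdf0 + 2 * p * (1 - p)
    u = rng.random((config.n_variants, config.n_individuals))
    genotypes = np.where(u < cdf0, 0, np.where(u < cdf1, 1, 2)).astype(np.int16)
    individuals = [f"ind{k:04d}" for k in range(config.n_individuals)]
    return GenotypeMatrix(layout.panel, individuals, genotypes)


def _expected_signal(genotypes: np.ndarray, layout: CohortLayout) -> np.ndarray:
    expected = np.zeros(layout.chrom_length)
    for v, iv in enumerate(layout.panel):
        lo, hi = layout.region_bounds[v]
        expected[lo - 1 : hi] = layout.depths[v]
        expected[iv.start - 1 : iv.end] = layout.depths[v] * (genotypes[v] / 2.0)
    return expected


def _add_noise(
    expected: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.noise == "none":
        return expected.copy()
    if config.noise == "poisson":
        return rng.poisson(expected).astype(float)
    # gamma-Poisson mixture: mean mu, variance mu + dispersion * mu^2
    alpha = config.nb_dispersion
    if alpha <= 0:
        return rng.poisson(expected).astype(float)
    mu = np.where(expected > 0, expected, 0.0)
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(shape=1.0 / alpha, scale=alpha * mu[pos])
    return rng.poisson(lam).astype(float)


def simulate_profile(
    genotypes: np.ndarray,
    config: SimulationConfig,
    layout: Optional[CohortLayout] = None,
    individual_index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> SignalProfile:
    """Read-depth profile for one individual's genotype vector.

    Expected signal inside a deletion is the region depth scaled by
    intact copies / 2; outside deletions it is the region depth (exons) or
    zero (introns).
    """
    if layout is None:
        layout = CohortLayout.from_config(config)
    if rng is None:
        rng = _rng(config, 2, individual_index)
    expected = _expected_signal(np.asarray(genotypes), layout)
    return SignalProfile(config.chrom, _add_noise(expected, config, rng))


def simulate_hic(
    config: SimulationConfig,
    genotypes: np.ndarray,
    layout: Optional[CohortLayout] = None,
    individual_index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Symmetric Hi-C contact matrix for one individual.

    Background follows a distance-decay kernel ``depth / (1 + |i - j|)``;
    every bin overlapping a deletion has its row and column scaled by
    intact copies / 2, so a homozygous deletion empties its bins.
    """
    if layout is None:
        layout = CohortLayout.from_config(config)
    if rng is None:
        rng = _rng(config, 3, individual_index)
    bin_size = config.hic_bin_size
    n_bins = layout.chrom_length // bin_size
    idx = np.arange(n_bins)
    background = config.hic_depth / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    factors = np.ones(n_bins)
    for v, iv in enumerate(layout.panel):
        lo_bin = (iv.start - 1) // bin_size
        hi_bin = min(n_bins - 1, (iv.end - 1) // bin_size)
        if lo_bin < n_bins:
            f = np.asarray(genotypes)[v] / 2.0
            factors[lo_bin : hi_bin + 1] = np.minimum(factors[lo_bin : hi_bin + 1], f)
    expected = background * np.outer(factors, factors)
    if config.noise == "none":
        return expected
    upper = rng.poisson(np.triu(expected)).astype(float)
    return upper + np.triu(upper, 1).T


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[TruthSet, Cohort, MappabilityProfile]:
    """Full cohort: truth genotypes, one signal profile per individual, and
    the shared multi-mappability track."""
    layout = CohortLayout.from_config(config)
    gmatrix = simulate_genotypes(config, layout)
    profiles = {
        ind: [simulate_profile(gmatrix.genotypes[:, k], config, layout, individual_index=k)]
        for k, ind in enumerate(gmatrix.individuals)
    }
    cohort = Cohort(list(gmatrix.individuals), profiles)
    truth = TruthSet(
        panel=layout.panel,
        genotypes=gmatrix,
        identity={ind: ind for ind in gmatrix.individuals},
        layout=layout,
    )
    return truth, cohort, layout.mappability()


def expand_by_resampling(
    gmatrix: GenotypeMatrix, n_out: int, seed: int
) -> GenotypeMatrix:
    """Grow a genotype dataset: each simulated individual draws, per
    variant, a genotype from that variant's empirical genotype frequencies
    (independently across variants)."""
    if gmatrix.n_variants == 0:
        raise ValueError("cannot resample an empty genotype matrix")
    rng = np.random.default_rng(seed)
    freqs = gmatrix.freqs
    out = np.full((gmatrix.n_variants, n_out), -1, dtype=np.int16)
    u = rng.random((gmatrix.n_variants, n_out))
    for v in range(gmatrix.n_variants):
        row = freqs[v]
        if np.isnan(row).any():
            continue  # all-missing variant stays missing
        cdf = np.cumsum(row)
        out[v] = np.searchsorted(cdf, u[v], side="right").clip(0, 2)
    individuals = [f"sim{k:05d}" for k in range(n_out)]
    return GenotypeMatrix(gmatrix.panel, individuals, out)
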