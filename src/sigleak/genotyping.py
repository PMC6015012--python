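"""Extremity-based deletion genotyping from signal profiles.

A deletion carried on both haplotypes leaves a sharp dip in read depth.
Candidates passing mappability/neighbor-signal filters are sorted by how
extreme their dip is — ascending self-to-neighbor ratio (rho) for small
deletions, ascending mean signal (s_bar) for large ones — and the top n
are assigned homozygous genotypes (call = 0).  The method never calls
heterozygotes; downstream linking tolerates that.

Also here: de novo candidate discovery by tiling the genome (5 bp windows
within exons for small deletions, 1000 bp genome-wide windows for large
ones) and conversion of Hi-C contact matrices to marginal signal profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import DeletionPanel, GenomicInterval, SignalProfile
from .features import UNDEFINED, compute_features, interval_mean

SMALL_WINDOW = 5
LARGE_WINDOW = 1000


@dataclass
class GenotypingParams:
    """Filtering and ranking parameters.

    Defaults are the standard working set: mappability ceiling 1.5,
    neighbor-signal floor 10, balance floor 0.5; accuracy is insensitive
    to these as long as they are not made too stringent.
    """

    m_max: float = 1.5
    tau_min: float = 10.0
    eta_min: float = 0.5
    n_top: int = 50

    def __post_init__(self) -> None:
        if self.m_max <= 0:
            raise ValueError("m_max must be positive")
        if self.tau_min < 0:
            raise ValueError("tau_min must be non-negative")
        if not 0 <= self.eta_min <= 1:
            raise ValueError("eta_min must be in [0, 1]")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


@dataclass
class GenotypeCall:
    interval: GenomicInterval
    call: int  # always 0: homozygous deletion
    rank: int  # 1-based position in the sorted extremity list
    score: float  # the sort key (rho for small, s_bar for large)


def _top_calls(scored: List[Tuple[float, GenomicInterval]], n_top: int) -> List[GenotypeCall]:
    # sort by score, ties by (chrom, start, end, id) for determinism
    scored.sort(key=lambda t: (t[0], t[1]))
    if len(scored) < n_top:
        warnings.warn(
            f"only {len(scored)} candidates survive the filters (n_top={n_top})"
        )
    return [
        GenotypeCall(iv, call=0, rank=r + 1, score=score)
        for r, (score, iv) in enumerate(scored[:n_top])
    ]


def genotype_small_deletions(
    profile: SignalProfile,
    mappability: SignalProfile,
    panel: DeletionPanel,
    params: GenotypingParams = GenotypingParams(),
) -> List[GenotypeCall]:
    """Call homozygous small deletions by ascending rho.

    Candidates must satisfy m_bar < m_max (high mappability), tau > tau_min
    (high neighbor signal) and eta > eta_min (high neighbor balance);
    records with UNDEFINED features fail the filters.
    """
    records, _ = compute_features(profile, mappability, panel)
    scored: List[Tuple[float, GenomicInterval]] = []
    for r in records:
        if r.rho is UNDEFINED or r.eta is UNDEFINED:
            continue
        if r.m_bar < params.m_max and r.tau > params.tau_min and r.eta > params.eta_min:
            scored.append((r.rho, r.interval))
    return _top_calls(scored, params.n_top)


def genotype_large_deletions(
    profile: SignalProfile,
    mappability: SignalProfile,
    panel: DeletionPanel,
    m_max: float = 1.5,
    n_top: int = 50,
) -> List[GenotypeCall]:
    """Call homozygous large deletions by ascending mean signal.

    Only the mappability filter applies; broad deletions need no
    neighborhood support.  Works on base-pair or binned (e.g. Hi-C
    marginal) profiles.
    """
    scored: List[Tuple[float, GenomicInterval]] = []
    for iv in panel:
        try:
            m_bar = interval_mean(mappability, iv)
            s_bar = interval_mean(profile, iv)
        except (ValueError, IndexError):
            continue
        if m_bar < m_max:
            scored.append((s_bar, iv))
    return _top_calls(scored, n_top)


def make_denovo_windows(
    mode: str,
    exonic_regions: Optional[Sequence[GenomicInterval]] = None,
    chrom_lengths: Optional[Dict[str, int]] = None,
    window: Optional[int] = None,
) -> DeletionPanel:
    """Candidate deletions when no panel is available: non-overlapping
    tiling windows, 5 bp within exons (small) or 1000 bp genome-wide
    (large); trailing partial windows are dropped."""
    if mode == "small":
        if not exonic_regions:
            raise ValueError("small-deletion discovery requires exonic regions")
        w = window or SMALL_WINDOW
        intervals = []
        for exon in sorted(exonic_regions):
            start = exon.start
            while start + w - 1 <= exon.end:
                intervals.append(
                    GenomicInterval(
                        exon.chrom, start, start + w - 1,
                        id=f"{exon.chrom}:{start}-{start + w - 1}",
                    )
                )
                start += w
        return DeletionPanel(intervals, source="denovo_small")
    if mode == "large":
        if not chrom_lengths:
            raise ValueError("large-deletion discovery requires chromosome lengths")
        w = window or LARGE_WINDOW
        intervals = []
        for chrom in sorted(chrom_lengths):
            start = 1
            while start + w - 1 <= chrom_lengths[chrom]:
                intervals.append(
                    GenomicInterval(
                        chrom, start, start + w - 1,
                        id=f"{chrom}:{start}-{start + w - 1}",
                    )
                )
                start += w
        return DeletionPanel(intervals, source="denovo_large")
    raise ValueError(f"unknown discovery mode {mode!r}")


def hic_to_profile(
    matrix: np.ndarray, bin_size: int, chrom: str = "chr1"
) -> SignalProfile:
    """Collapse a Hi-C contact matrix to a 1-D profile of column sums.

    Bins overlapping a homozygous deletion lose their contacts, so the
    marginal dips there just as read depth does.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"contact matrix must be square, got shape {matrix.shape}")
    if matrix.size and matrix.min() < 0:
        raise ValueError("contact matrix entries must be non-negative")
    return SignalProfile(chrom, matrix.sum(axis=0), resolution=bin_size)
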