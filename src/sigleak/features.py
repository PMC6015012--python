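"""Per-deletion signal features and their log2 bins.

For a deletion ``[i, j]`` on a read-depth profile **S** with multi-mappability
track **M**, five features summarize how visible the deletion is:

* ``s_bar`` — mean signal inside the deletion;
* ``m_bar`` — mean multi-mappability inside the deletion;
* ``rho``   — self-to-neighbor ratio, ``2 * s_bar / (s_left + s_right)``
  where ``s_left``/``s_right`` are the flank means; a dip gives small rho;
* ``eta``   — neighbor balance, ``min(s_right/s_left, s_left/s_right)``;
  near 1 means a symmetric, trustworthy flank context;
* ``tau``   — mean neighborhood signal, ``0.5 * (s_left + s_right)``.

Features are binned by ``floor(log2(x))``; non-positive values (including
zero denominators) map to a distinguished UNDEFINED bin, represented as
``None`` throughout and written as ``NA``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import DeletionPanel, GenomicInterval, SignalProfile, neighborhood_of

#: Sentinel for features/bins with a zero denominator or non-positive log.
UNDEFINED = None


@dataclass
class DeletionFeatures:
    interval: GenomicInterval
    s_bar: float
    m_bar: float
    rho: Optional[float]
    eta: Optional[float]
    tau: float
    bins: Tuple[Optional[int], ...]

    def has_undefined_bin(self) -> bool:
        return any(b is UNDEFINED for b in self.bins)


def interval_mean(profile: SignalProfile, interval: GenomicInterval) -> float:
    """Mean signal over the interval (sum / length in profile entries)."""
    return float(profile.slice(interval).mean())


def _flank_means(profile: SignalProfile, interval: GenomicInterval) -> Tuple[float, float]:
    left, right = neighborhood_of(interval)
    return interval_mean(profile, left), interval_mean(profile, right)


def self_to_neighbor_ratio(
    profile: SignalProfile, interval: GenomicInterval
) -> Optional[float]:
    """rho = 2 * s_bar / (s_left + s_right); UNDEFINED when both flanks are 0."""
    s_left, s_right = _flank_means(profile, interval)
    denom = s_left + s_right
    if denom == 0:
        return UNDEFINED
    return 2.0 * interval_mean(profile, interval) / denom


def neighbor_balance(
    profile: SignalProfile, interval: GenomicInterval
) -> Optional[float]:
    """eta = min(s_right/s_left, s_left/s_right); UNDEFINED if a flank is 0."""
    s_left, s_right = _flank_means(profile, interval)
    if s_left == 0 or s_right == 0:
        return UNDEFINED
    return min(s_right / s_left, s_left / s_right)


def neighbor_mean(profile: SignalProfile, interval: GenomicInterval) -> float:
    """tau = 0.5 * (s_left + s_right)."""
    s_left, s_right = _flank_means(profile, interval)
    return 0.5 * (s_left + s_right)


def log2_bin(x: Optional[float]) -> Optional[int]:
    """floor(log2(x)) for x > 0; UNDEFINED otherwise."""
    if x is UNDEFINED or x <= 0:
        return UNDEFINED
    return math.floor(math.log2(x))


def features_for_interval(
    profile: SignalProfile,
    mappability: SignalProfile,
    interval: GenomicInterval,
) -> DeletionFeatures:
    """Compute the five features and their bins for one deletion.

    Raises for intervals whose neighborhood is out of bounds (or shorter
    than 3 bp); :func:`compute_features` turns that into a skip.
    """
    s_left, s_right = _flank_means(profile, interval)
    s_bar = interval_mean(profile, interval)
    m_bar = interval_mean(mappability, interval)
    denom = s_left + s_right
    rho = UNDEFINED if denom == 0 else 2.0 * s_bar / denom
    eta = (
        UNDEFINED
        if (s_left == 0 or s_right == 0)
        else min(s_right / s_left, s_left / s_right)
    )
    tau = 0.5 * denom
    bins = tuple(log2_bin(v) for v in (s_bar, m_bar, rho, eta, tau))
    return DeletionFeatures(interval, s_bar, m_bar, rho, eta, tau, bins)


def compute_features(
    profile: SignalProfile,
    mappability: SignalProfile,
    panel: DeletionPanel,
) -> Tuple[List[DeletionFeatures], List[str]]:
    """Features for every panel interval whose neighborhood is computable.

    Returns ``(records, skipped_ids)``; intervals with flanks outside the
    profile extent (or length < 3) are skipped, never clamped, so features
    stay comparable across deletions.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    records: List[DeletionFeatures] = []
    skipped: List[str] = []
    for iv in panel:
        if iv.chrom != profile.chrom:
            skipped.append(iv.id)
            continue
        try:
            records.append(features_for_interval(profile, mappability, iv))
        except (ValueError, IndexError):
            skipped.append(iv.id)
    if not records:
        warnings.warn("no panel interval had a computable neighborhood")
    return records, skipped


def feature_frame(records: Sequence[DeletionFeatures]):
    """Feature table as a pandas DataFrame (UNDEFINED -> NA)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "id": r.interval.id,
                "s_bar": r.s_bar,
                "m_bar": r.m_bar,
                "rho": np.nan if r.rho is UNDEFINED else r.rho,
                "eta": np.nan if r.eta is UNDEFINED else r.eta,
                "tau": r.tau,
                "bin_s": pd.NA if r.bins[0] is UNDEFINED else r.bins[0],
                "bin_m": pd.NA if r.bins[1] is UNDEFINED else r.bins[1],
                "bin_rho": pd.NA if r.bins[2] is UNDEFINED else r.bins[2],
                "bin_eta": pd.NA if r.bins[3] is UNDEFINED else r.bins[3],
                "bin_tau": pd.NA if r.bins[4] is UNDEFINED else r.bins[4],
            }
        )
    return pd.DataFrame(rows)
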