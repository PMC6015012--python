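"""Anonymization of signal profiles by median filtering at known deletions.

Read-depth dips over deletions are what leaks genotypes; replacing the
signal inside each known deletion with a local median erases dips while
leaving the rest of the profile untouched.  The filter treats the deletion
like an impulse-noise artifact whose extent is known: for each position
``a`` in a deletion ``[i, j]`` of length ``l``, the replacement is the
median of the original values in the window ``[a - l, a + l]`` (clamped at
chromosome edges) EXCLUDING the deletion's own positions.  Masking the
corrupted region out of the window is what makes the output independent of
the genotype: every individual's filtered interior is the same order
statistic of flanking signal, whether or not they carry the deletion, so a
dip of any depth — including the full-width zero dip of a homozygous
deletion — is removed rather than merely trimmed.  Every output value is
an element of its window; the filter invents no new values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import DeletionPanel, GenomicInterval, SignalProfile
from .features import UNDEFINED, self_to_neighbor_ratio


def _window_median(values: np.ndarray) -> float:
    """Sort-and-pick-middle median; even counts (edge-clamped windows)
    take the lower-middle element, deterministically."""
    k = (values.size - 1) // 2
    return float(np.partition(values, k)[k])


def median_filter_interval(
    profile: SignalProfile,
    interval: GenomicInterval,
    half_window: Optional[int] = None,
    exclude_interval: bool = True,
) -> SignalProfile:
    """Median-filter the positions inside one deletion interval.

    Only positions ``a`` in ``[i, j]`` are replaced; each takes the median
    of the ORIGINAL values in ``[a - h, a + h]`` (clamped to the
    chromosome), with the deletion's own positions masked out of the
    window by default.  The default half-window ``h`` is the interval
    length, so at least ``l`` flanking values vote at every position.

    ``exclude_interval=False`` gives the plain (unmasked) running median;
    note a window that mostly covers the dip returns dip values, so the
    unmasked variant only attenuates dips narrower than the interval.
    """
    i, j = interval.start, interval.end
    n = profile.n_positions
    if profile.resolution != 1:
        raise ValueError("median filtering operates on base-pair profiles")
    if interval.chrom != profile.chrom or i < 1 or j > n:
        raise IndexError(f"interval [{i},{j}] outside profile extent (1..{n})")
    h = interval.length if half_window is None else half_window
    if h < 0:
        raise ValueError("half_window must be non-negative")
    out = profile.values.copy()
    src = profile.values
    for a in range(i, j + 1):
        lo = max(1, a - h)
        hi = min(n, a + h)
        if exclude_interval:
            idx = np.r_[lo - 1 : i - 1, j : hi]
        else:
            idx = np.arange(lo - 1, hi)
        if idx.size == 0:
            raise ValueError(
                f"window around position {a} holds no values outside [{i},{j}]; "
                "increase half_window"
            )
        out[a - 1] = _window_median(src[idx])
    return SignalProfile(profile.chrom, out, profile.resolution)


@dataclass
class AnonymizationReport:
    n_intervals_filtered: int = 0
    n_positions_modified: int = 0
    fraction_modified: float = 0.0
    #: per interval: (id, rho before, rho after); rho is None when undefined
    rho_changes: List[Tuple[str, Optional[float], Optional[float]]] = field(
        default_factory=list
    )


def anonymize_profile(
    profile: SignalProfile,
    panel: DeletionPanel,
    half_window: Optional[int] = None,
) -> Tuple[SignalProfile, AnonymizationReport]:
    """Median-filter every panel deletion, in coordinate order.

    Overlapping intervals are processed sequentially: a later filter sees
    the output of an earlier one.  The report records, per interval, the
    self-to-neighbor ratio before and after (where computable) so the dip
    removal can be audited, plus the fraction of positions modified.
    """
    report = AnonymizationReport()
    current = profile.copy()
    original = profile.values
    for iv in panel:
        if iv.chrom != profile.chrom or iv.end > profile.n_positions:
            continue
        rho_before = _safe_rho(current, iv)
        current = median_filter_interval(current, iv, half_window=half_window)
        rho_after = _safe_rho(current, iv)
        report.n_intervals_filtered += 1
        report.rho_changes.append((iv.id, rho_before, rho_after))
    modified = int((current.values != original).sum())
    report.n_positions_modified = modified
    report.fraction_modified = modified / max(1, len(original))
    return current, report


def _safe_rho(profile: SignalProfile, interval: GenomicInterval) -> Optional[float]:
    try:
        rho = self_to_neighbor_ratio(profile, interval)
    except (ValueError, IndexError):
        return None
    return None if rho is UNDEFINED else rho


def report_frame(report: AnonymizationReport):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": iv_id,
                "rho_before": np.nan if b is None else b,
                "rho_after": np.nan if a is None else a,
            }
            for iv_id, b, a in report.rho_changes
        ]
    )
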