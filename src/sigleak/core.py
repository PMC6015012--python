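"""Core domain types and coordinate conventions.

All coordinates are 1-based and inclusive internally: a deletion between
genomic positions ``i`` and ``j`` is the interval ``[i, j]`` with length
``j - i + 1``.  BED/bedGraph files (0-based, half-open) are converted on
read/write by :mod:`sigleak.io`; nothing outside that module should have
to think about the convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np

#: Sentinel genotype code for a missing call (``.`` in TSV files).
MISSING: int = -1

#: The three genotype codes: number of INTACT copies of the region.
#: 0 = homozygous deletion, 1 = heterozygous, 2 = no deletion.
GENOTYPE_VALUES = (0, 1, 2)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval ``[start, end]``.

    Ordering is (chrom, start, end, id), which is also the tie-break rule
    used everywhere a deterministic interval order is needed.
    """

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed(self) -> tuple:
        """(chrom, 0-based start, half-open end) for BED output."""
        return (self.chrom, self.start - 1, self.end)

    @classmethod
    def from_bed(cls, chrom: str, bed_start: int, bed_end: int, id: str = "") -> "GenomicInterval":
        return cls(chrom=chrom, start=bed_start + 1, end=bed_end, id=id)

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping base pairs (0 if disjoint or different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class SignalProfile:
    """A per-position (or per-bin) non-negative read-depth vector.

    ``values[k]`` holds the signal for positions
    ``[k * resolution + 1, (k + 1) * resolution]``; for base-pair profiles
    (``resolution == 1``) that is simply position ``k + 1``.
    """

    chrom: str
    values: np.ndarray
    resolution: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be a 1-D vector")
        if self.resolution < 1:
            raise ValueError("resolution must be a positive integer")
        if self.values.size and self.values.min() < 0:
            raise ValueError("signal values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_positions(self) -> int:
        """Chromosome extent covered, in base pairs."""
        return self.values.size * self.resolution

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        """Values covering ``interval`` (a view where possible).

        Positions are mapped to bins for coarse-resolution profiles.
        """
        if interval.chrom != self.chrom:
            raise ValueError(
                f"interval on {interval.chrom} queried against profile on {self.chrom}"
            )
        lo = (interval.start - 1) // self.resolution
        hi = (interval.end - 1) // self.resolution
        if interval.start < 1 or hi >= self.values.size:
            raise IndexError(
                f"interval [{interval.start},{interval.end}] outside profile extent "
                f"(1..{self.n_positions})"
            )
        return self.values[lo : hi + 1]

    def copy(self) -> "SignalProfile":
        return SignalProfile(self.chrom, self.values.copy(), self.resolution)


#: A multi-mappability track has the same shape as a signal profile; high
#: values mark repeat-like regions where read placement is untrustworthy.
MappabilityProfile = SignalProfile


@dataclass
class DeletionPanel:
    """An ordered set of deletion intervals with unique identifiers."""

    intervals: List[GenomicInterval]
    source: str = "known_panel"

    _SOURCES = ("known_panel", "denovo_small", "denovo_large")

    def __post_init__(self) -> None:
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown panel source {self.source!r}")
        self.intervals = sorted(self.intervals)
        ids = [iv.id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            raise ValueError("panel interval ids must be unique")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, idx: int) -> GenomicInterval:
        return self.intervals[idx]

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def index_of(self) -> Dict[str, int]:
        """Map interval id -> position in the sorted panel."""
        return {iv.id: k for k, iv in enumerate(self.intervals)}


@dataclass
class GenotypeMatrix:
    """Genotypes for a panel of deletions over a set of individuals.

    ``genotypes`` is a (variants x individuals) integer array with values
    in {0, 1, 2} (intact copies) or :data:`MISSING`.
    """

    panel: DeletionPanel
    individuals: List[str]
    genotypes: np.ndarray
    _freqs: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.shape != (len(self.panel), len(self.individuals)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.panel)} variants x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            v, i = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[v, i]} at variant {v}, "
                f"individual {self.individuals[i]}"
            )

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """(variants x 3) empirical genotype frequencies over non-missing calls.

        Rows of all-missing variants are NaN.
        """
        if self._freqs is None:
            counts = np.stack(
                [(self.genotypes == g).sum(axis=1) for g in GENOTYPE_VALUES], axis=1
            ).astype(float)
            totals = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                self._freqs = np.where(totals > 0, counts / totals, np.nan)
        return self._freqs

    def all_missing_variants(self) -> List[int]:
        return [int(v) for v in np.flatnonzero((self.genotypes == MISSING).all(axis=1))]

    def column(self, individual: str) -> np.ndarray:
        return self.genotypes[:, self.individuals.index(individual)]

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        panel = DeletionPanel(
            [self.panel.intervals[k] for k in indices], source=self.panel.source
        )
        return GenotypeMatrix(panel, list(self.individuals), self.genotypes[indices, :])


@dataclass
class Cohort:
    """A signal-profile dataset: per individual, one profile per chromosome
    and possibly one per assay mark (pooled downstream)."""

    individuals: List[str]
    profiles: Dict[str, List[SignalProfile]]
    sensitive_labels: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        for ind in self.individuals:
            if not self.profiles.get(ind):
                raise ValueError(f"individual {ind!r} has no signal profile")
        chrom_sets = {
            ind: frozenset(p.chrom for p in profs)
            for ind, profs in self.profiles.items()
        }
        if len(set(chrom_sets.values())) > 1:
            raise ValueError("profile chromosomes inconsistent across individuals")

    def pooled(self, individual: str) -> SignalProfile:
        return pool_profiles(self.profiles[individual])


def pool_profiles(profiles: Sequence[SignalProfile]) -> SignalProfile:
    """Sum signal profiles elementwise (e.g., multiple histone marks of one
    individual are pooled into a single track before genotyping)."""
    if not profiles:
        raise ValueError("cannot pool an empty list of profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if p.chrom != first.chrom:
            raise ValueError("pooled profiles must share a chromosome")
        if p.resolution != first.resolution or len(p) != len(first):
            raise ValueError("pooled profiles must share resolution and length")
    total = np.sum([p.values for p in profiles], axis=0)
    return SignalProfile(first.chrom, total, first.resolution)


def neighborhood_of(interval: GenomicInterval) -> tuple:
    """Flanking neighborhood of a deletion ``[i, j]``.

    Returns ``(left, right)`` with ``left = [2i-j+1, i-1]`` and
    ``right = [j+1, 2j-i+1]``: the right flank has the interval's length,
    the left flank two positions fewer.  Intervals shorter than 3 bp have
    an empty left flank and are rejected, as are intervals whose left
    flank would start before position 1; callers exclude such intervals
    from feature computation rather than clamping.
    """
    i, j = interval.start, interval.end
    if interval.length < 3:
        raise ValueError(
            f"interval [{i},{j}] is too short for a neighborhood (needs length >= 3)"
        )
    left_start = 2 * i - j + 1
    if left_start < 1:
        raise ValueError(
            f"left flank of [{i},{j}] starts at {left_start}, before the chromosome"
        )
    left = GenomicInterval(interval.chrom, left_start, i - 1, id=f"{interval.id}.L")
    right = GenomicInterval(interval.chrom, j + 1, 2 * j - i + 1, id=f"{interval.id}.R")
    return left, right
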