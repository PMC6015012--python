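"""Leakage metrics: genome-wide predictability and characterizing information.

Genome-wide predictability (pi_GW) of a deletion genotype is the empirical
conditional probability of the true genotype given the deletion's five
binned signal features, estimated over all deletions of one individual's
genome.  Individual characterizing information (ICI) is the surprisal,
``-log2(frequency)``, of a genotype in the population: rare genotypes carry
more identifying bits.

A circular-shuffle baseline destroys the association between genotypes and
signal while preserving the signal's value multiset, so the predictability
gained from real profiles can be compared against chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import GENOTYPE_VALUES, MISSING, GenomicInterval, SignalProfile
from .features import DeletionFeatures

BinKey = Tuple[Optional[int], ...]


@dataclass
class PredictabilityModel:
    """Empirical genotype distribution per occupied feature-bin cell.

    ``bin_table[cell]`` is a length-3 probability vector over genotypes
    {0, 1, 2}; ``support[cell]`` counts the deletions in the cell so users
    can discount singleton cells (a deletion alone in its cell predicts
    itself with probability 1).
    """

    bin_table: Dict[BinKey, np.ndarray]
    support: Dict[BinKey, int]


def fit_predictability(
    features: Sequence[DeletionFeatures],
    genotypes: Sequence[int],
    include_undefined: bool = True,
) -> PredictabilityModel:
    """Estimate P(genotype | binned features) for one individual.

    Each deletion contributes to its own cell (self-inclusion).  Records
    whose bins include the UNDEFINED sentinel form their own cells — on a
    read-depth profile, "signal exactly zero" is itself highly informative
    for homozygous deletions — unless ``include_undefined`` is False, in
    which case they are dropped.  MISSING genotypes are always dropped.
    """
    if len(features) != len(genotypes):
        raise ValueError("features and genotypes must align on the same panel")
    counts: Dict[BinKey, np.ndarray] = {}
    for feat, g in zip(features, genotypes):
        if g == MISSING:
            continue
        if g not in GENOTYPE_VALUES:
            raise ValueError(f"invalid genotype {g}")
        if not include_undefined and feat.has_undefined_bin():
            continue
        cell = counts.setdefault(feat.bins, np.zeros(3))
        cell[g] += 1
    if not counts:
        raise ValueError("no computable (feature, genotype) records to fit on")
    bin_table = {k: v / v.sum() for k, v in counts.items()}
    support = {k: int(v.sum()) for k, v in counts.items()}
    return PredictabilityModel(bin_table, support)


def predictability(
    model: PredictabilityModel,
    features_of_deletion: DeletionFeatures,
    true_genotype: int,
) -> Optional[float]:
    """pi_GW = P(true genotype | the deletion's bin cell); None if the cell
    is unoccupied in the model (excluded from summaries)."""
    dist = model.bin_table.get(features_of_deletion.bins)
    if dist is None:
        return None
    return float(dist[true_genotype])


def pi_gw_per_deletion(
    model: PredictabilityModel,
    features: Sequence[DeletionFeatures],
    genotypes: Sequence[int],
) -> List[Optional[float]]:
    """Vector of pi_GW values (None where the cell is unoccupied or the
    genotype is missing)."""
    out: List[Optional[float]] = []
    for feat, g in zip(features, genotypes):
        if g == MISSING:
            out.append(None)
        else:
            out.append(predictability(model, feat, g))
    return out


def ici(genotype_frequency: float) -> float:
    """Individual characterizing information, in bits: -log2(frequency).

    Strictly decreasing in frequency; a genotype everyone shares
    (frequency 1) carries 0 bits.
    """
    if genotype_frequency <= 0:
        raise ValueError("genotype frequency must be positive")
    return -math.log2(genotype_frequency)


def circular_shuffle(
    profile: SignalProfile,
    offset: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SignalProfile:
    """Rotate the profile circularly: output[k] = input[(k - offset) mod n].

    Preserves the value multiset (hence genome-wide mean and variance)
    while destroying positional associations.  Either an explicit offset
    or a seeded generator must be supplied.
    """
    n = len(profile)
    if offset is None:
        if rng is None:
            raise ValueError("provide an offset or a seeded random generator")
        offset = int(rng.integers(0, n))
    if not 0 <= offset <= n:
        raise ValueError(f"offset must be in [0, {n}]")
    return SignalProfile(profile.chrom, np.roll(profile.values, offset), profile.resolution)


@dataclass
class LeakageRecord:
    interval: GenomicInterval
    genotype: int
    pi_gw: Optional[float]
    ici: Optional[float]
    cell_support: Optional[int]


def leakage_records(
    features: Sequence[DeletionFeatures],
    genotypes: Sequence[int],
    model: PredictabilityModel,
    genotype_freqs: Optional[np.ndarray] = None,
) -> List[LeakageRecord]:
    """Per-deletion leakage report for one individual.

    ``genotype_freqs`` is the (variants x 3) population genotype-frequency
    table aligned with ``features``; when given, each record carries the
    ICI of the individual's genotype at that variant.
    """
    records = []
    for k, (feat, g) in enumerate(zip(features, genotypes)):
        if g == MISSING:
            continue
        pi = predictability(model, feat, g)
        support = model.support.get(feat.bins)
        bits: Optional[float] = None
        if genotype_freqs is not None:
            f = float(genotype_freqs[k, g])
            if f > 0:
                bits = ici(f)
        records.append(LeakageRecord(feat.interval, int(g), pi, bits, support))
    return records


def leakage_frame(records: Sequence[LeakageRecord]):
    """Scatter-ready leakage table (ici vs pi_gw) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "id": r.interval.id,
                "genotype": r.genotype,
                "pi_gw": np.nan if r.pi_gw is None else r.pi_gw,
                "ici": np.nan if r.ici is None else r.ici,
                "cell_support": 0 if r.cell_support is None else r.cell_support,
            }
            for r in records
        ]
    )
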