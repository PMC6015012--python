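"""Genotype-distance linking attack and its evaluation.

The attacker genotypes deletions from each individual's signal profile,
matches that panel against a genotype dataset's panel by interval overlap,
counts genotype mismatches (Hamming distance over the common variants) to
every individual in the genotype dataset, and links each query to the
argmin.  The first distance gap — second-best minus best distance — scores
how reliable each linking is; sensitivity and positive predictive value
are computed over a gap threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import MISSING, DeletionPanel, GenotypeMatrix, SignalProfile
from .genotyping import GenotypeCall, GenotypingParams, genotype_large_deletions, genotype_small_deletions


@dataclass
class PanelMatch:
    """Pairing of a signal-side panel (P_S) with a genotype-side panel (P_G).

    ``pairs`` holds (index in P_S, index in P_G, overlap bp); deletions
    overlapping by at least one base pair are assumed to be the same
    variant, and each P_S interval is matched at most once (largest
    overlap wins; ties go to the smallest P_G start).
    """

    pairs: List[Tuple[int, int, int]]

    def __len__(self) -> int:
        return len(self.pairs)


def match_panels(panel_s: DeletionPanel, panel_g: DeletionPanel) -> PanelMatch:
    """Match each P_S interval to the best-overlapping P_G interval."""
    g_by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    for gi, iv in enumerate(panel_g):
        g_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gi))
    pairs: List[Tuple[int, int, int]] = []
    for si, siv in enumerate(panel_s):
        best: Optional[Tuple[int, int, int]] = None  # (-overlap, g_start, gi)
        for g_start, g_end, gi in g_by_chrom.get(siv.chrom, ()):
            if g_start > siv.end:
                break  # sorted by start: nothing further can overlap
            ov = min(siv.end, g_end) - max(siv.start, g_start) + 1
            if ov >= 1:
                key = (-ov, g_start, gi)
                if best is None or key < best:
                    best = key
        if best is not None:
            pairs.append((si, best[2], -best[0]))
    return PanelMatch(pairs)


def genotype_distance(calls_k: Sequence[int], g_l: Sequence[int]) -> int:
    """Hamming distance between two genotype vectors on the common set;
    positions MISSING in either vector are skipped."""
    a = np.asarray(calls_k)
    b = np.asarray(g_l)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must align on the same common set")
    if a.size == 0:
        raise ValueError("empty common set")
    valid = (a != MISSING) & (b != MISSING)
    return int(((a != b) & valid).sum())


@dataclass
class LinkResult:
    query_id: str
    linked_id: str
    linked_index: int
    d1: int
    d2: Optional[int]
    gap: Optional[int]  # d2 - d1; None when < 2 candidates
    n_compared: int
    correct: Optional[bool] = None


def link_individual(
    calls_k: Sequence[int], gmatrix: GenotypeMatrix, query_id: str = ""
) -> LinkResult:
    """Link one query genotype vector (over P_G variants, MISSING where the
    attacker made no call) to the nearest genotype-dataset individual."""
    q = np.asarray(calls_k).reshape(-1, 1)
    if q.shape[0] != gmatrix.n_variants:
        raise ValueError("query vector must cover the genotype panel's variants")
    if not (q != MISSING).any():
        raise ValueError("query vector has no called variants")
    G = gmatrix.genotypes
    valid = (q != MISSING) & (G != MISSING)
    dists = ((q != G) & valid).sum(axis=0)
    order = np.argsort(dists, kind="stable")  # argmin ties -> dataset order
    best = int(order[0])
    d1 = int(dists[best])
    if len(order) > 1:
        d2 = int(dists[order[1]])
        gap: Optional[int] = d2 - d1
    else:
        d2, gap = None, None
    return LinkResult(
        query_id=query_id,
        linked_id=gmatrix.individuals[best],
        linked_index=best,
        d1=d1,
        d2=d2,
        gap=gap,
        n_compared=int(valid[:, best].sum()),
    )


def calls_to_query_vector(
    calls: Sequence[GenotypeCall],
    panel_s: DeletionPanel,
    match: PanelMatch,
    n_g_variants: int,
    n_variants: Optional[int] = None,
) -> np.ndarray:
    """Project genotyper calls onto the genotype panel's variant axis.

    Matched variants the attacker called get genotype 0; everything else
    is MISSING (only genotyped deletions enter the distance).  When
    ``n_variants`` is given, only the ``n_variants`` best-ranked calls are
    used — the "number of variants used in the attack" axis.
    """
    used = sorted(calls, key=lambda c: c.rank)
    if n_variants is not None:
        used = used[:n_variants]
    called_ids = {c.interval.id for c in used}
    s_index = panel_s.index_of()
    called_s = {s_index[cid] for cid in called_ids if cid in s_index}
    out = np.full(n_g_variants, MISSING, dtype=np.int16)
    for si, gi, _ov in match.pairs:
        if si in called_s:
            out[gi] = 0
    return out


def attack_cohort(
    profiles: Dict[str, SignalProfile],
    mappability: SignalProfile,
    panel_s: DeletionPanel,
    gmatrix: GenotypeMatrix,
    params: GenotypingParams = GenotypingParams(),
    mode: str = "small",
    n_variants: Optional[int] = None,
    truth: Optional[Dict[str, str]] = None,
) -> List[LinkResult]:
    """End-to-end linking attack: genotype every query profile, then link
    it against the genotype dataset.  ``truth`` (query id -> true genotype
    dataset id) fills the ``correct`` flags when known."""
    match = match_panels(panel_s, gmatrix.panel)
    if len(match) == 0:
        raise ValueError("panels share no overlapping deletions; linking impossible")
    results = []
    for query_id in sorted(profiles):
        profile = profiles[query_id]
        if mode == "small":
            calls = genotype_small_deletions(profile, mappability, panel_s, params)
        elif mode == "large":
            calls = genotype_large_deletions(
                profile, mappability, panel_s, m_max=params.m_max, n_top=params.n_top
            )
        else:
            raise ValueError(f"unknown genotyping mode {mode!r}")
        query = calls_to_query_vector(
            calls, panel_s, match, gmatrix.n_variants, n_variants
        )
        if not (query != MISSING).any():
            continue
        res = link_individual(query, gmatrix, query_id=query_id)
        if truth is not None:
            res.correct = res.linked_id == truth.get(query_id)
        results.append(res)
    return results


def evaluate_linking(
    results: Sequence[LinkResult],
    truth: Dict[str, str],
    gap_threshold: float = 0.0,
) -> Tuple[float, Optional[float], float]:
    """(sensitivity, PPV, accuracy) of gap-thresholded linkings.

    sensitivity = correct links with gap > threshold, over ALL individuals;
    PPV = correct links with gap > threshold, over links passing the
    threshold (None when nothing passes); accuracy ignores the threshold.
    """
    n_all = len(results)
    if n_all == 0:
        raise ValueError("no link results to evaluate")
    correct_flags = [
        (r.linked_id == truth[r.query_id]) if r.correct is None else r.correct
        for r in results
    ]
    passing = [
        (c, r) for c, r in zip(correct_flags, results)
        if r.gap is not None and r.gap > gap_threshold
    ]
    n_pass = len(passing)
    n_correct_pass = sum(c for c, _ in passing)
    sensitivity = n_correct_pass / n_all
    ppv = (n_correct_pass / n_pass) if n_pass else None
    accuracy = sum(correct_flags) / n_all
    return sensitivity, ppv, accuracy


def mark_vulnerable(results: Sequence[LinkResult], truth: Dict[str, str]) -> Set[str]:
    """Individuals whose profile links back to their own genotypes."""
    return {r.query_id for r in results if r.linked_id == truth[r.query_id]}


def random_selection_ppv(
    results: Sequence[LinkResult],
    truth: Dict[str, str],
    size: int,
    n_rounds: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean PPV over random subsets of linkings of the given size — the
    baseline a gap-based selection must beat."""
    if rng is None:
        rng = np.random.default_rng()
    if size < 1 or size > len(results):
        raise ValueError("subset size must be in [1, n_results]")
    flags = np.array([r.linked_id == truth[r.query_id] for r in results])
    ppvs = [
        flags[rng.choice(len(flags), size=size, replace=False)].mean()
        for _ in range(n_rounds)
    ]
    return float(np.mean(ppvs))


def filter_variants_by_genotype_freq(
    gmatrix: GenotypeMatrix, min_genotype_freq: float = 0.01
) -> List[int]:
    """Indices of variants whose least-frequent OBSERVED genotype has
    population frequency >= the cutoff.

    Very rare genotypes uniquely identify their carriers; dropping such
    variants removes that bias from panel-level analyses.
    """
    keep = []
    freqs = gmatrix.freqs
    for v in range(gmatrix.n_variants):
        row = freqs[v]
        if np.isnan(row).all():
            continue
        observed = row[row > 0]
        if observed.size and observed.min() >= min_genotype_freq:
            keep.append(v)
    return keep


def link_frame(results: Sequence[LinkResult]):
    """Link results as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "linked_id": r.linked_id,
                "d1": r.d1,
                "d2": -1 if r.d2 is None else r.d2,
                "gap": np.nan if r.gap is None else r.gap,
                "n_compared": r.n_compared,
                "correct": "" if r.correct is None else str(bool(r.correct)),
            }
            for r in results
        ]
    )
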