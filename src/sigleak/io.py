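"""Readers and writers for the text formats the toolkit touches.

bedGraph is the signal interchange (textual, diffable); BED carries panels;
genotype matrices travel as TSV.  All coordinate conversion between on-disk
conventions (BED/bedGraph: 0-based, half-open) and the internal one
(1-based, inclusive) happens here and nowhere else.  Writers prepend
provenance comment lines (``# sigleak ...``) that every reader skips.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    MISSING,
    DeletionPanel,
    GenomicInterval,
    GenotypeMatrix,
    SignalProfile,
)


def provenance_lines(subcommand: str, **params) -> List[str]:
    parts = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return [f"# sigleak {__version__} {subcommand} {parts}".rstrip()]


def _data_lines(path: str) -> Iterable[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path: str) -> Dict[str, SignalProfile]:
    """Dense per-chromosome signal vectors from a 4-column bedGraph.

    Runs are expanded; positions not covered by any run are 0.  Overlapping
    runs, negative values, and malformed lines are errors.
    """
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative signal value {value}")
        if end <= start or start < 0:
            raise ValueError(f"{path}:{lineno}: bad interval [{start},{end})")
        runs.setdefault(chrom, []).append((start, end, value))

    profiles: Dict[str, SignalProfile] = {}
    for chrom, chrom_runs in runs.items():
        chrom_runs.sort()
        prev_end = 0
        for start, end, _ in chrom_runs:
            if start < prev_end:
                raise ValueError(f"{path}: overlapping bedGraph runs on {chrom} at {start}")
            prev_end = end
        values = np.zeros(chrom_runs[-1][1])
        for start, end, value in chrom_runs:
            values[start:end] = value
        profiles[chrom] = SignalProfile(chrom, values)
    return profiles


def write_bedgraph(
    profiles: Dict[str, SignalProfile] | SignalProfile,
    path: str,
    header: Optional[Sequence[str]] = None,
) -> None:
    """Run-length-encoded bedGraph covering the full profile extent (zero
    runs included, so read/write round-trips preserve length)."""
    if isinstance(profiles, SignalProfile):
        profiles = {profiles.chrom: profiles}
    with open(path, "w") as fh:
        for line in header or provenance_lines("write_bedgraph"):
            fh.write(line + "\n")
        for chrom in sorted(profiles):
            p = profiles[chrom]
            if p.resolution != 1:
                raise ValueError("bedGraph output requires base-pair resolution")
            values = p.values
            if values.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:g}\n")


# ---------------------------------------------------------------------------
# BED panels

def read_bed(path: str, source: str = "known_panel") -> DeletionPanel:
    """Deletion panel from BED (0-based half-open); column 4, when present,
    is the interval id, otherwise ids are synthesized from coordinates."""
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom, bstart, bend = fields[0], int(fields[1]), int(fields[2])
        iv_id = fields[3] if len(fields) > 3 else f"{chrom}:{bstart + 1}-{bend}"
        intervals.append(GenomicInterval.from_bed(chrom, bstart, bend, id=iv_id))
    return DeletionPanel(intervals, source=source)


def write_bed(panel: DeletionPanel, path: str, header: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for line in header or provenance_lines("write_bed", source=panel.source):
            fh.write(line + "\n")
        for iv in panel:
            chrom, bstart, bend = iv.to_bed()
            fh.write(f"{chrom}\t{bstart}\t{bend}\t{iv.id}\n")


# ---------------------------------------------------------------------------
# Genotype matrices

def read_genotype_tsv(path: str, source: str = "known_panel") -> GenotypeMatrix:
    """Genotype matrix TSV: header ``chrom start end <id1> <id2> ...``,
    coordinates 1-based inclusive, cells in {0, 1, 2, .}."""
    header: Optional[List[str]] = None
    intervals: List[GenomicInterval] = []
    rows: List[List[int]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            if fields[:3] != ["chrom", "start", "end"]:
                raise ValueError(f"{path}:{lineno}: header must start with chrom/start/end")
            header = fields
            continue
        if len(fields) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        intervals.append(GenomicInterval(chrom, start, end, id=f"{chrom}:{start}-{end}"))
        row = []
        for col, cell in enumerate(fields[3:], start=4):
            if cell == ".":
                row.append(MISSING)
            elif cell in ("0", "1", "2"):
                row.append(int(cell))
            else:
                raise ValueError(
                    f"{path}:{lineno}: invalid genotype {cell!r} in column {col}"
                )
        rows.append(row)
    if header is None:
        raise ValueError(f"{path}: missing header line")
    individuals = header[3:]
    genotypes = np.asarray(rows, dtype=np.int16).reshape(len(intervals), len(individuals))
    return GenotypeMatrix(DeletionPanel(intervals, source=source), individuals, genotypes)


def write_genotype_tsv(
    gmatrix: GenotypeMatrix, path: str, header: Optional[Sequence[str]] = None
) -> None:
    with open(path, "w") as fh:
        for line in header or provenance_lines("write_genotype_tsv"):
            fh.write(line + "\n")
        fh.write("\t".join(["chrom", "start", "end", *gmatrix.individuals]) + "\n")
        for v, iv in enumerate(gmatrix.panel):
            cells = [
                "." if g == MISSING else str(int(g)) for g in gmatrix.genotypes[v]
            ]
            fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end), *cells]) + "\n")


# ---------------------------------------------------------------------------
# Hi-C matrices

def read_hic_matrix(path: str, format: str = "dense", atol: float = 1e-8) -> np.ndarray:
    """Dense symmetric contact matrix from whitespace-delimited text.

    ``dense``: a square matrix, checked for symmetry.  ``triplet``:
    ``bin_i bin_j count`` rows, completed symmetrically; conflicting
    duplicate entries are errors.
    """
    if format == "dense":
        matrix = np.loadtxt(path, comments="#", ndmin=2)
        if matrix.shape[0] != matrix.shape[1]:
            raise ValueError(f"{path}: dense matrix is not square {matrix.shape}")
        if matrix.size and matrix.min() < 0:
            raise ValueError(f"{path}: negative contact count")
        if not np.allclose(matrix, matrix.T, atol=atol):
            raise ValueError(f"{path}: dense matrix is not symmetric")
        return matrix
    if format == "triplet":
        entries: Dict[Tuple[int, int], float] = {}
        max_bin = -1
        for lineno, line in _data_lines(path):
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 triplet columns")
            i, j, count = int(fields[0]), int(fields[1]), float(fields[2])
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative contact count")
            if i < 0 or j < 0:
                raise ValueError(f"{path}:{lineno}: negative bin index")
            key = (min(i, j), max(i, j))
            if key in entries and abs(entries[key] - count) > atol:
                raise ValueError(f"{path}:{lineno}: conflicting duplicate entry {key}")
            entries[key] = count
            max_bin = max(max_bin, i, j)
        n = max_bin + 1
        matrix = np.zeros((n, n))
        for (i, j), count in entries.items():
            matrix[i, j] = count
            matrix[j, i] = count
        return matrix
    raise ValueError(f"unknown Hi-C matrix format {format!r}")


def write_hic_dense(matrix: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%g")


# ---------------------------------------------------------------------------
# Tables (features, leakage, links, calls)

def write_table(frame: pd.DataFrame, path: str, header: Optional[Sequence[str]] = None) -> None:
    """TSV with provenance comment lines; NA cells rendered as 'NA'."""
    with open(path, "w") as fh:
        for line in header or provenance_lines("write_table"):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def read_calls_tsv(path: str):
    """Genotype calls written by the CLI back into GenotypeCall objects."""
    from .genotyping import GenotypeCall

    frame = read_table(path)
    calls = []
    for row in frame.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), id=str(row.id))
        calls.append(GenotypeCall(iv, call=int(row.call), rank=int(row.rank), score=float(row.score)))
    return calls


def calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "id": c.interval.id,
                "call": c.call,
                "rank": c.rank,
                "score": c.score,
            }
            for c in calls
        ]
    )


def read_truth_tsv(path: str) -> Dict[str, str]:
    """Two-column query_id -> true_id map."""
    truth = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 truth columns")
        truth[fields[0]] = fields[1]
    return truth


def write_truth_tsv(truth: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines("write_truth_tsv"):
            fh.write(line + "\n")
        for query_id in sorted(truth):
            fh.write(f"{query_id}\t{truth[query_id]}\n")
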