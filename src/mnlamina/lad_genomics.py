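"""Lamina-associated-domain (LAD) coverage per chromosome.

LADs and blacklist regions arrive as BED intervals (0-based, half-open);
chromosome lengths as a two-column TSV. The LAD percentage of a
chromosome is the blacklist-subtracted LAD length divided by the
blacklist-subtracted chromosome length, times 100.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicIntervalSet",
    "read_bed",
    "read_chrom_lengths",
    "normalize_intervals",
    "subtract_intervals",
    "lad_percent",
]


class GenomicIntervalSet:
    """Sorted, merged 0-based half-open intervals keyed by chromosome."""

    def __init__(self, intervals: dict[str, np.ndarray] | None = None):
        self.intervals: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                self.intervals[chrom] = _merge(np.asarray(arr, dtype=np.int64))

    def total_length(self, chrom: str | None = None) -> int:
        chroms = [chrom] if chrom is not None else list(self.intervals)
        total = 0
        for c in chroms:
            arr = self.intervals.get(c)
            if arr is not None and len(arr):
                total += int((arr[:, 1] - arr[:, 0]).sum())
        return total

    def __eq__(self, other) -> bool:
        if set(self.intervals) != set(other.intervals):
            return False
        return all(np.array_equal(self.intervals[c], other.intervals[c])
                   for c in self.intervals)


def _merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or adjacent half-open intervals."""
    if arr.size == 0:
        return arr.reshape(0, 2)
    if np.any(arr[:, 0] < 0):
        raise ValueError("negative coordinate")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("interval start must be < end")
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:  # overlap or adjacency
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=np.int64)


def normalize_intervals(raw: dict[str, list | np.ndarray]) -> GenomicIntervalSet:
    """Build a normalised interval set from raw (start, end) lists."""
    return GenomicIntervalSet({c: np.asarray(v, dtype=np.int64).reshape(-1, 2)
                               for c, v in raw.items()})


def subtract_intervals(a: GenomicIntervalSet,
                       b: GenomicIntervalSet) -> GenomicIntervalSet:
    """Per-chromosome set difference a \\ b, result normalised."""
    out: dict[str, np.ndarray] = {}
    for chrom, arr in a.intervals.items():
        sub = b.intervals.get(chrom)
        if sub is None or len(sub) == 0:
            out[chrom] = arr.copy()
            continue
        pieces = []
        for start, end in arr:
            cursor = start
            for bs, be in sub:
                if be <= cursor or bs >= end:
                    continue
                if bs > cursor:
                    pieces.append((cursor, bs))
                cursor = max(cursor, be)
                if cursor >= end:
                    break
            if cursor < end:
                pieces.append((cursor, end))
        out[chrom] = np.asarray(pieces, dtype=np.int64).reshape(-1, 2)
    return GenomicIntervalSet(out)


def read_bed(path: str | Path) -> GenomicIntervalSet:
    """Read a 3+ column BED file into a normalised interval set."""
    raw: dict[str, list] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        raw.setdefault(chrom, []).append((int(start), int(end)))
    return normalize_intervals(raw)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     comment="#")
    lengths = dict(zip(df["chrom"], df["length"].astype(int)))
    if any(v <= 0 for v in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    return lengths


def lad_percent(lads: GenomicIntervalSet,
                blacklist: GenomicIntervalSet,
                lengths: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome LAD percentage after blacklist subtraction.

    Blacklisted base pairs are removed from both the LAD coverage
    (numerator) and the chromosome length (denominator). Chromosomes in
    ``lengths`` without LAD intervals report 0%.
    """
    clean = subtract_intervals(lads, blacklist)
    rows = []
    for chrom, length in lengths.items():
        bl = blacklist.total_length(chrom)
        eff = length - bl
        if eff <= 0:
            raise ZeroDivisionError(
                f"blacklist covers all of {chrom}; LAD%% undefined")
        lad_bp = clean.total_length(chrom)
        rows.append({"chromosome": chrom, "lad_bp": lad_bp,
                     "effective_length_bp": eff,
                     "lad_percent": 100.0 * lad_bp / eff})
    return pd.DataFrame(rows)
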