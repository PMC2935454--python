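"""Platform-exclusive coverage analysis for two-platform assemblies.

When a genome is sequenced on two platforms with orthogonal coverage
biases, part of the assembly is covered by only one of them.  This module
partitions contig positions into both/only-A/only-B/neither classes,
summarizes coverage-gap lengths, and provides the uniform-coverage
expectation for the missed fraction (the Poisson zero class e^-c at
fold-coverage c).

A position counts as covered at depth >= 1.  Intervals are 0-based
half-open, sorted, disjoint and maximal, and can round-trip through BED.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

Interval = tuple[int, int]


@dataclass
class CoverageTrack:
    """Per-position read depth for each platform over one contig."""

    contig: str
    length: int
    depth_by_platform: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.depth_by_platform.items():
            arr = np.asarray(arr)
            if arr.shape != (self.length,):
                raise ValueError(f"depth array for {name} does not span the contig")
            if (arr < 0).any():
                raise ValueError(f"negative depth in track {name}")
            self.depth_by_platform[name] = arr


@dataclass
class GapStats:
    count: int
    mean_length: float | None
    histogram: dict[int, int]
    short_gap_count: int  # gaps below the short-gap cutoff (default <20 b)


def intervals_from_mask(mask: np.ndarray) -> list[Interval]:
    """Maximal True runs of a boolean vector as half-open intervals."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def coverage_partition(track: CoverageTrack) -> dict[str, list[Interval]]:
    """Partition [0, length) into coverage classes for a two-platform track.

    Returns ``{"both": ..., "only:<A>": ..., "only:<B>": ..., "neither": ...}``
    with platforms in sorted name order.
    """
    platforms = sorted(track.depth_by_platform)
    if len(platforms) != 2:
        raise ValueError("coverage_partition requires exactly two platforms")
    a, b = platforms
    cov_a = track.depth_by_platform[a] >= 1
    cov_b = track.depth_by_platform[b] >= 1
    return {
        "both": intervals_from_mask(cov_a & cov_b),
        f"only:{a}": intervals_from_mask(cov_a & ~cov_b),
        f"only:{b}": intervals_from_mask(cov_b & ~cov_a),
        "neither": intervals_from_mask(~cov_a & ~cov_b),
    }


def gap_stats(gaps: Sequence[Interval], short_cutoff: int = 20) -> GapStats:
    """Count/mean/length-histogram of an interval set (1-base bins), with a
    summary count of short gaps (< ``short_cutoff`` bases)."""
    lengths = [e - s for s, e in gaps]
    hist = dict(sorted(Counter(lengths).items()))
    return GapStats(
        count=len(lengths),
        mean_length=(sum(lengths) / len(lengths)) if lengths else None,
        histogram=hist,
        short_gap_count=sum(1 for l in lengths if l < short_cutoff),
    )


def expected_uncovered_fraction(c: float) -> float:
    """Fraction of the genome expected to receive zero reads under uniform
    coverage at ``c`` fold: the Poisson zero class e^-c."""
    if c < 0:
        raise ValueError("fold-coverage must be non-negative")
    return math.exp(-c)


def exclusive_fraction(tracks: Sequence[CoverageTrack]) -> dict[str, float]:
    """Genome fraction covered exclusively by each platform across tracks.

    Returns per-platform fractions keyed by platform name plus
    ``"single_platform_total"`` (their sum).
    """
    if not tracks:
        raise ValueError("no coverage tracks given")
    platforms = sorted(tracks[0].depth_by_platform)
    exclusive = {p: 0 for p in platforms}
    total = 0
    for track in tracks:
        if sorted(track.depth_by_platform) != platforms:
            raise ValueError("inconsistent platform sets across tracks")
        part = coverage_partition(track)
        for p in platforms:
            exclusive[p] += total_length(part[f"only:{p}"])
        total += track.length
    out = {p: exclusive[p] / total for p in platforms}
    out["single_platform_total"] = sum(exclusive.values()) / total
    return out


# ---------------------------------------------------------------------------
# BED round-trip
# ---------------------------------------------------------------------------


def write_bed(intervals_by_contig: Mapping[str, Sequence[Interval]], handle: IO[str]) -> None:
    for contig in sorted(intervals_by_contig):
        for s, e in intervals_by_contig[contig]:
            handle.write(f"{contig}\t{s}\t{e}\n")


def read_bed(handle: IO[str]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for line in handle:
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        contig, s, e = line.split("\t")[:3]
        out.setdefault(contig, []).append((int(s), int(e)))
    for intervals in out.values():
        intervals.sort()
    return out
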