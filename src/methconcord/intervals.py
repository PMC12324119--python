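"""Minimal interval algebra over 0-based half-open intervals.

Intervals are ``(start, end)`` tuples with ``start < end``; a *track* is a
per-chromosome dict mapping chromosome name to a sorted, merged list of
intervals. All catalog construction reduces to merge/subtract/complement on
these tracks.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable

Interval = tuple[int, int]
Track = dict[str, list[Interval]]

__all__ = [
    "Interval",
    "Track",
    "merge",
    "subtract",
    "complement",
    "intersect",
    "union_tracks",
    "contains",
    "total_length",
    "clip_track",
]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """a minus b; both inputs must be sorted and merged."""
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement(a: list[Interval], chrom_len: int) -> list[Interval]:
    return subtract([(0, chrom_len)], a)


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def union_tracks(*tracks: Track) -> Track:
    chroms = set()
    for t in tracks:
        chroms.update(t)
    return {
        c: merge(iv for t in tracks for iv in t.get(c, [])) for c in chroms
    }


def contains(intervals: list[Interval], pos: int) -> bool:
    """Membership test against a sorted, merged interval list."""
    i = bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def clip_track(track: Track, genome_sizes: dict[str, int]) -> Track:
    """Clip intervals to [0, chrom length); drop unknown chromosomes."""
    out: Track = {}
    for chrom, ivs in track.items():
        if chrom not in genome_sizes:
            continue
        n = genome_sizes[chrom]
        clipped = [(max(0, s), min(e, n)) for s, e in ivs]
        out[chrom] = merge((s, e) for s, e in clipped if s < e)
    return out
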