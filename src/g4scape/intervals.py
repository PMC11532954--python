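"""Sorted-interval primitives shared across the scanner, feature map and mutation overlap.

All coordinates are 0-based half-open (BED convention). Intervals are plain
``(start, end)`` tuples; genome-wide collections carry the chromosome as a
leading element, ``(chrom, start, end)``.
"""
from __future__ import annotations

import heapq
import logging
from bisect import bisect_right
from collections import defaultdict
from collections.abc import Iterable, Sequence

logger = logging.getLogger(__name__)

Interval = tuple[int, int]
GenomicInterval = tuple[str, int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, non-overlapping list.

    Abutting intervals ([0,5), [5,8)) are coalesced.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_size(intervals: Iterable[Interval]) -> int:
    """Total number of bases covered by the union of ``intervals``."""
    return sum(e - s for s, e in merge_intervals(intervals))


def point_in_merged(merged: Sequence[Interval], pos: int) -> bool:
    """Half-open containment of a point in a merged (sorted, disjoint) list."""
    i = bisect_right(merged, (pos, float("inf"))) - 1
    return i >= 0 and merged[i][0] <= pos < merged[i][1]


def overlapping_segments(
    merged: Sequence[Interval], start: int, end: int
) -> list[Interval]:
    """Clipped pieces of ``merged`` that fall inside [start, end)."""
    out: list[Interval] = []
    i = bisect_right(merged, (start, float("inf"))) - 1
    if i < 0:
        i = 0
    for s, e in merged[i:]:
        if s >= end:
            break
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out.append((lo, hi))
    return out


def _check_sorted(
    ivs: Sequence[GenomicInterval], name: str
) -> list[tuple[str, int, int, int]]:
    """Attach original indices; sort (with a log note) if input is unsorted."""
    indexed = [(c, int(s), int(e), i) for i, (c, s, e) in enumerate(ivs)]
    keys = [(c, s) for c, s, _e, _i in indexed]
    if keys != sorted(keys):
        logger.warning("intersect: input %r not sorted by (chrom, start); sorting internally", name)
        indexed.sort(key=lambda t: (t[0], t[1], t[2]))
    return indexed


def sweep_intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """All pairs of intervals from ``a`` and ``b`` overlapping by >= 1 bp.

    Linear sweep with the same semantics as ``bedtools intersect``: returns
    ``(index_in_a, index_in_b, overlap_length)`` triples sorted by the input
    indices. Inputs must be sorted by (chrom, start); unsorted input is sorted
    internally and logged.
    """
    ia = _check_sorted(a, "a")
    ib = _check_sorted(b, "b")
    by_chrom_a: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    by_chrom_b: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for c, s, e, i in ia:
        by_chrom_a[c].append((s, e, i))
    for c, s, e, i in ib:
        by_chrom_b[c].append((s, e, i))

    out: list[tuple[int, int, int]] = []
    for chrom in sorted(set(by_chrom_a) & set(by_chrom_b)):
        av, bv = by_chrom_a[chrom], by_chrom_b[chrom]
        pa = pb = 0
        active_a: list[tuple[int, int, int]] = []  # (end, start, idx) heaps
        active_b: list[tuple[int, int, int]] = []
        while pa < len(av) or pb < len(bv):
            take_a = pb >= len(bv) or (pa < len(av) and av[pa][0] <= bv[pb][0])
            if take_a:
                s, e, i = av[pa]
                pa += 1
                while active_b and active_b[0][0] <= s:
                    heapq.heappop(active_b)
                for eb, sb, j in active_b:
                    out.append((i, j, min(e, eb) - s))
                heapq.heappush(active_a, (e, s, i))
            else:
                s, e, j = bv[pb]
                pb += 1
                while active_a and active_a[0][0] <= s:
                    heapq.heappop(active_a)
                for ea, sa, i in active_a:
                    out.append((i, j, min(e, ea) - s))
                heapq.heappush(active_b, (e, s, j))
    out.sort()
    return out
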