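"""Half-open interval algebra on sorted coordinate arrays.

All coordinates throughout the package are 0-based half-open ``[start, end)``.
Interval lists are kept *maximally merged*: sorted, non-overlapping and
non-adjacent (two intervals with ``a.end == b.start`` are fused), so the
complement never contains zero-length intervals.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge an arbitrary interval collection into maximally merged form.

    Overlapping and half-open-adjacent intervals are fused; empty intervals
    are dropped.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return []
    out: list[Interval] = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s <= pe:  # overlap or adjacency
            if e > pe:
                out[-1] = (ps, e)
        else:
            out.append((s, e))
    return out


def complement_intervals(intervals: Sequence[Interval], length: int) -> list[Interval]:
    """Complement of a merged interval list within ``[0, length)``."""
    out: list[Interval] = []
    cursor = 0
    for s, e in intervals:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return out

def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total overlap (bp) between two merged interval lists."""
    i = j = 0
    out = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def clip_interval(start: int, end: int, length: int) -> Interval:
    return max(0, start), min(end, length)


class IntervalIndex:
    """Overlap queries against a merged interval list via binary search."""

    def __init__(self, intervals: Sequence[Interval]):
        self.intervals = list(intervals)
        self._starts = np.array([s for s, _ in intervals], dtype=np.int64)
        self._ends = np.array([e for _, e in intervals], dtype=np.int64)

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any indexed interval by >= 1 bp."""
        if end <= start or len(self.intervals) == 0:
            return False
        # first interval with end > start
        i = int(np.searchsorted(self._ends, start, side="right"))
        return i < len(self.intervals) and self._starts[i] < end

    def overlapping(self, start: int, end: int) -> list[int]:
        """Indices of all intervals overlapping [start, end)."""
        if end <= start or len(self.intervals) == 0:
            return []
        i = int(np.searchsorted(self._ends, start, side="right"))
        out = []
        while i < len(self.intervals) and self._starts[i] < end:
            out.append(i)
            i += 1
        return out

    def covers_point(self, pos: int) -> bool:
        return self.overlaps(pos, pos + 1)
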