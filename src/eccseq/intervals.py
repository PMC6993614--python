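"""Half-open interval arithmetic shared by detection, annotation and simulation.

All coordinates are 0-based half-open ``[start, end)``.  Merging uses
bedtools ``merge -d 0`` semantics: overlapping *or bookended* intervals
(``[0, 100)`` and ``[100, 200)``) collapse into one.
"""
from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(
    intervals: Iterable[tuple[int, int]], distance: int = 0
) -> list[tuple[int, int]]:
    """Union of intervals; intervals closer than or equal to ``distance`` merge."""
    out: list[list[int]] = []
    for start, end in sorted(intervals):
        if start > end:
            raise ValueError(f"invalid interval [{start}, {end})")
        if out and start <= out[-1][1] + distance:
            if end > out[-1][1]:
                out[-1][1] = end
        else:
            out.append([start, end])
    return [(s, e) for s, e in out]


def merge_tagged(
    items: Iterable[tuple[int, int, object]], distance: int = 0
) -> list[tuple[int, int, list]]:
    """Distance-``distance`` union keeping the payloads of merged members."""
    out: list[tuple[int, int, list]] = []
    cur: list | None = None
    for start, end, tag in sorted(items, key=lambda t: (t[0], t[1])):
        if start > end:
            raise ValueError(f"invalid interval [{start}, {end})")
        if cur is not None and start <= cur[1] + distance:
            cur[1] = max(cur[1], end)
            cur[2].append(tag)
        else:
            if cur is not None:
                out.append((cur[0], cur[1], cur[2]))
            cur = [start, end, [tag]]
    if cur is not None:
        out.append((cur[0], cur[1], cur[2]))
    return out


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total number of bases covered by the union of the intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Shared fraction of *both* intervals: min(ov/|a|, ov/|b|)."""
    ov = overlap_length(a, b)
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        raise ValueError("degenerate interval")
    return min(ov / la, ov / lb)


class IntervalIndex:
    """Sorted-array overlap queries against a fixed set of intervals.

    Query cost is O(log n + hits); intervals need not be disjoint.
    """

    def __init__(self, intervals: Sequence[tuple[int, int]]):
        import numpy as np

        ivs = sorted(intervals)
        self.starts = np.array([s for s, _ in ivs], dtype=np.int64)
        self.ends = np.array([e for _, e in ivs], dtype=np.int64)
        # running max of ends lets us bound the leftmost possible overlap
        self.max_end = (
            np.maximum.accumulate(self.ends) if len(ivs) else self.ends
        )

    def __len__(self) -> int:
        return len(self.starts)

    def overlaps(self, start: int, end: int, min_overlap: int = 1) -> bool:
        """True if any stored interval shares >= ``min_overlap`` bases with [start, end)."""
        return self.max_overlap(start, end) >= min_overlap

    def max_overlap(self, start: int, end: int) -> int:
        """Largest single-interval overlap with [start, end) (0 if none)."""
        import numpy as np

        if len(self.starts) == 0:
            return 0
        hi = int(np.searchsorted(self.starts, end, side="left"))
        best = 0
        for i in range(hi - 1, -1, -1):
            if self.max_end[i] <= start:
                break
            ov = min(self.ends[i], end) - max(self.starts[i], start)
            if ov > best:
                best = int(ov)
        return best

    def total_overlap(self, start: int, end: int) -> int:
        """Bases of [start, end) covered by the union of the stored intervals."""
        import numpy as np

        if len(self.starts) == 0:
            return 0
        hi = int(np.searchsorted(self.starts, end, side="left"))
        pieces = []
        for i in range(hi - 1, -1, -1):
            if self.max_end[i] <= start:
                break
            s = max(int(self.starts[i]), start)
            e = min(int(self.ends[i]), end)
            if e > s:
                pieces.append((s, e))
        return union_length(pieces)
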