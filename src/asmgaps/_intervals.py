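"""Tiny interval primitives shared across stages.

All intervals are 0-based half-open ``(start, end)`` pairs on a named
chromosome handled by the callers; these helpers work on the bare pairs.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge(intervals: Iterable[tuple[int, int]], join_adjacent: bool = True) -> list[tuple[int, int]]:
    """Merge overlapping (and, by default, abutting) intervals."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and (s < out[-1][1] or (join_adjacent and s == out[-1][1])):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def gap_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Base-pair distance between two intervals; 0 when they overlap or abut."""
    (a0, a1), (b0, b1) = a, b
    if a0 < b1 and b0 < a1:
        return 0
    return max(a0, b0) - min(a1, b1)


def point_distance(pos: int, iv: tuple[int, int]) -> int:
    """Distance from a point to an interval; 0 if the point lies inside."""
    s, e = iv
    if s <= pos < e:
        return 0
    return s - pos if pos < s else pos - (e - 1)


def min_point_distance(pos: int, intervals: Sequence[tuple[int, int]]) -> int | None:
    """Minimum distance from a point to any interval (None when empty).

    Linear scan; callers with big tracks pre-sort and bisect instead.
    """
    if not intervals:
        return None
    return min(point_distance(pos, iv) for iv in intervals)


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]
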