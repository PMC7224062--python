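"""Half-open interval helpers.

All internal coordinates are 0-based, half-open ``[start, end)``. Human-readable
and VCF output uses 1-based inclusive coordinates; the conversion happens only at
the serialization boundary.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def validate_intervals(
    intervals: Sequence[Interval],
    length: int | None = None,
    *,
    require_sorted: bool = True,
    require_disjoint: bool = True,
) -> list[Interval]:
    """Validate a list of half-open intervals, returning them as tuples.

    Raises ``ValueError`` on empty intervals, out-of-bounds coordinates,
    unsorted or overlapping intervals.
    """
    out: list[Interval] = []
    prev_end = None
    for iv in intervals:
        start, end = int(iv[0]), int(iv[1])
        if start < 0 or end <= start:
            raise ValueError(f"invalid interval [{start}, {end})")
        if length is not None and end > length:
            raise ValueError(f"interval [{start}, {end}) out of bounds for length {length}")
        if prev_end is not None:
            if require_sorted and start < out[-1][0]:
                raise ValueError("intervals are not sorted")
            if require_disjoint and start < prev_end:
                raise ValueError(f"intervals overlap at [{start}, {end})")
        out.append((start, end))
        prev_end = end
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def intersect(a: Interval, b: Interval) -> Interval | None:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    return (s, e) if s < e else None


def contains(iv: Interval, pos: int) -> bool:
    return iv[0] <= pos < iv[1]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent intervals into maximal disjoint ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
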