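"""Half-open interval arithmetic on integer genome coordinates.

All coordinates are 0-based half-open ``[start, end)``. These helpers back
the length rules for broad annotation types (operon/regulon/pathway/COG),
where overlapping transcription units contribute their nucleotide union.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or adjacent intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def union_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def complement(intervals: Iterable[Interval], genome_length: int) -> List[Interval]:
    """Maximal gaps of ``[0, genome_length)`` not covered by ``intervals``."""
    out: List[Interval] = []
    cursor = 0
    for s, e in merge(intervals):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < genome_length:
        out.append((cursor, genome_length))
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Positions in the union of ``a`` but not in the union of ``b``."""
    a_m = merge(a)
    b_m = merge(b)
    out: List[Interval] = []
    j = 0
    for s, e in a_m:
        cursor = s
        while j < len(b_m) and b_m[j][1] <= cursor:
            j += 1
        k = j
        while k < len(b_m) and b_m[k][0] < e:
            bs, be = b_m[k]
            if bs > cursor:
                out.append((cursor, bs))
            cursor = max(cursor, be)
            k += 1
        if cursor < e:
            out.append((cursor, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    a_m = merge(a)
    b_m = merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a_m) and j < len(b_m):
        s = max(a_m[i][0], b_m[j][0])
        e = min(a_m[i][1], b_m[j][1])
        if s < e:
            out.append((s, e))
        if a_m[i][1] <= b_m[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    """Non-empty intersection of two half-open intervals."""
    return s1 < e2 and s2 < e1
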