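"""Genomic intervals and elementary interval algebra.

All coordinates in this package are 0-based, half-open ``[start, end)``.
File readers and writers convert to and from the 1-based closed convention
of GFF3/GTF and BLAST tabular output at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

STRANDS = (PLUS, MINUS)


def opposite_strand(strand: str) -> str:
    if strand == PLUS:
        return MINUS
    if strand == MINUS:
        return PLUS
    raise ValueError(f"strand {strand!r} has no opposite")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded span on a contig, 0-based half-open.

    Parameters
    ----------
    contig : str
        Sequence identifier.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp on the same contig."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully inside this interval (same contig)."""
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.contig, self.start + offset, self.end + offset, self.strand
        )


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge overlapping or touching ``(start, end)`` pairs into a sorted,
    disjoint list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def complement_intervals(
    intervals: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Complement of a set of intervals within ``[lo, hi)``.

    Input intervals are clipped to the window first; the result is sorted
    and disjoint, and its union with the (merged) input tiles the window.
    """
    if hi <= lo:
        return []
    clipped = [
        (max(s, lo), min(e, hi)) for s, e in intervals if s < hi and e > lo
    ]
    merged = merge_intervals(clipped)
    out: list[tuple[int, int]] = []
    cursor = lo
    for s, e in merged:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        out.append((cursor, hi))
    return out


def intersect_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Pairwise intersection of two disjoint sorted interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    a = sorted(a)
    b = sorted(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)
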