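"""Genomic-interval arithmetic: merge, closest feature, containment, and BED I/O.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
SNP positions arriving from GWAS-catalog-style tables are 1-based and are
converted to a single-base interval ``[pos-1, pos)`` before any distance logic.

Distance convention (stated because tools differ): a point inside an interval
has distance 0; a point one base outside either edge has distance 1
(``p0 >= end -> p0 - end + 1``; ``p0 < start -> start - p0``). This matches the
``bedtools closest -d`` adjacency-is-one convention. Strand is carried but
ignored by all distance logic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence


class BedParseError(ValueError):
    """Raised on a malformed BED line; message carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """One genomic feature: chromatin state, TFBS cluster, transcript, or gene span."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    name: str = "."
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def contains(self, chrom: str, p0: int) -> bool:
        """True iff the 0-based position ``p0`` lies inside the interval."""
        return chrom == self.chrom and self.start <= p0 < self.end

    def __len__(self) -> int:
        return self.end - self.start


#: Sentinel returned by :func:`closest` when no interval shares the chromosome.
NO_NEIGHBOR = (None, None, [])


@dataclass
class IntervalSet:
    """A collection of intervals, sortable by (chrom, start, end)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    sorted_flag: bool = False

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def sort(self) -> "IntervalSet":
        if not self.sorted_flag:
            self.intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
            self.sorted_flag = True
        return self

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        self.sort()
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def merge(ivset: IntervalSet) -> IntervalSet:
    """Collapse overlapping *and* book-ended intervals into disjoint runs.

    Union-preserving: every covered base stays covered exactly once. Adjacent
    intervals (``end == start``) are merged, so output intervals are separated
    by at least one uncovered base. Names of merged members are joined with
    ','; idempotent.
    """
    merged: list[GenomicInterval] = []
    for chrom, ivs in ivset.by_chrom().items():
        cur_start, cur_end, names = ivs[0].start, ivs[0].end, [ivs[0].name]
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, iv.end)
                if iv.name not in names:
                    names.append(iv.name)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, ",".join(names)))
                cur_start, cur_end, names = iv.start, iv.end, [iv.name]
        merged.append(GenomicInterval(chrom, cur_start, cur_end, ",".join(names)))
    return IntervalSet(merged, sorted_flag=True)


def point_distance(p0: int, iv: GenomicInterval) -> int:
    """Distance between a 0-based position and an interval on the same chromosome."""
    if iv.start <= p0 < iv.end:
        return 0
    if p0 >= iv.end:
        return p0 - iv.end + 1
    return iv.start - p0


def closest(
    point: tuple[str, int], ivset: IntervalSet, *, one_based: bool = True
) -> tuple[Optional[GenomicInterval], Optional[int], list[GenomicInterval]]:
    """Nearest interval to a point, with all ties at the minimal distance.

    Returns ``(primary, distance, ties)``; the primary tie is the one with the
    lowest (chrom, start). ``NO_NEIGHBOR`` when the chromosome carries no
    interval. ``one_based`` says how to read ``point[1]`` (SNP tables are
    1-based; internal callers may pass 0-based).
    """
    chrom, pos = point
    p0 = pos - 1 if one_based else pos
    per_chrom = ivset.by_chrom()
    if chrom not in per_chrom:
        return NO_NEIGHBOR
    ivs = per_chrom[chrom]
    # Sorted by start: binary search narrows the scan, then sweep outward.
    starts = [iv.start for iv in ivs]
    idx = bisect.bisect_right(starts, p0)
    best = None
    # Ends are not sorted, so an interval starting far left may still reach the
    # point; scan everything left of the insertion index (linear, desk scale).
    candidates = []
    for i in range(idx - 1, -1, -1):
        iv = ivs[i]
        d = point_distance(p0, iv)
        candidates.append((d, iv))
        if best is None or d < best:
            best = d
    for i in range(idx, len(ivs)):
        iv = ivs[i]
        d = point_distance(p0, iv)
        candidates.append((d, iv))
        if best is None or d < best:
            best = d
        if iv.start - p0 > best:
            break
    ties = sorted((iv for d, iv in candidates if d == best), key=lambda iv: (iv.chrom, iv.start, iv.end))
    return ties[0], best, ties


def annotate_containment(
    points: Sequence[tuple[str, int]], ivset: IntervalSet, *, one_based: bool = True
) -> dict[tuple[str, int], list[str]]:
    """Map each point to the names of every interval containing it (may be empty).

    Overlapping, unmerged intervals each contribute their own name.
    """
    per_chrom = ivset.by_chrom()
    out: dict[tuple[str, int], list[str]] = {}
    for point in points:
        chrom, pos = point
        p0 = pos - 1 if one_based else pos
        names: list[str] = []
        for iv in per_chrom.get(chrom, []):
            if iv.start > p0:
                break
            if iv.contains(chrom, p0):
                names.append(iv.name)
        out[point] = names
    return out


def containing_intervals(
    point: tuple[str, int], ivset: IntervalSet, *, one_based: bool = True
) -> list[GenomicInterval]:
    """All intervals containing the point, in coordinate order."""
    chrom, pos = point
    p0 = pos - 1 if one_based else pos
    hits = []
    for iv in ivset.by_chrom().get(chrom, []):
        if iv.start > p0:
            break
        if iv.contains(chrom, p0):
            hits.append(iv)
    return hits


def read_bed(path, *, skip_track_lines: bool = True) -> IntervalSet:
    """Read BED3/BED4/BED6 (tab-separated, no header); track/browser lines skipped."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (skip_track_lines and line.startswith(("track", "browser", "#"))):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 else "."
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 else "."
            try:
                intervals.append(GenomicInterval(parts[0], start, end, name, score, strand))
            except ValueError as exc:
                # Report positions 1-based for humans.
                raise BedParseError(
                    f"{path}:{lineno}: bad interval (1-based start {start + 1})"
                ) from exc
    return IntervalSet(intervals)


def write_bed(ivset: IntervalSet, path) -> None:
    """Write BED with as many columns as the intervals carry (name always, score/strand if set)."""
    with open(path, "w") as fh:
        for iv in ivset.sort():
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def total_covered_bases(ivset: IntervalSet) -> int:
    """Total bases covered by the union of the set (via merge)."""
    return sum(len(iv) for iv in merge(ivset))
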