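"""Genomic interval algebra and region-file I/O shared by every pipeline stage.

All coordinates are 0-based half-open (the BED convention).  Formats that use
1-based positions (association tables) are converted at their parser boundary,
never downstream.  Strand is carried on intervals but deliberately ignored by
merge and intersect: responsive regions are defined on either strand.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "merge_regions",
    "intersect_min_overlap",
    "interval_length",
    "gene_relative_interval",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "IntersectResult",
]

_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-anchored 0-based half-open span ``[start, end)``.

    Ordering (and hence :class:`RegionSet` sort order) is by
    ``(contig, start, end)``; name, score and strand are annotation only.
    """

    contig: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}"


class RegionSet:
    """An ordered collection of :class:`GenomicInterval` on one assembly.

    Intervals are kept sorted by ``(contig, start, end)``.  Duplicates are
    permitted; :func:`merge_regions` produces the disjoint union.
    """

    __slots__ = ("intervals", "genome_tag")

    def __init__(
        self, intervals: Iterable[GenomicInterval] = (), genome_tag: str = ""
    ) -> None:
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.contig, iv.start, iv.end))
        )
        self.genome_tag = genome_tag

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals and self.genome_tag == other.genome_tag

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSet({len(self)} intervals, genome_tag={self.genome_tag!r})"

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.contig, None)
        return list(seen)

    def deduplicated(self) -> "RegionSet":
        """Drop intervals with identical (contig, start, end)."""
        out: list[GenomicInterval] = []
        last = None
        for iv in self.intervals:
            key = (iv.contig, iv.start, iv.end)
            if key != last:
                out.append(iv)
            last = key
        return RegionSet(out, self.genome_tag)


def interval_length(iv: GenomicInterval) -> int:
    """Span length in bp (``end - start``)."""
    return iv.length


def gene_relative_interval(
    offset_start: int, offset_end: int, tss: int = 0, contig: str = "gene_axis"
) -> GenomicInterval:
    """Build an interval from gene-relative offsets on a synthetic axis.

    Offsets like "-245 kb to -176 kb relative to the TSS" become an ordinary
    interval anchored at ``tss`` so that locus-relative arithmetic (deletion
    sizes, VR spans) is expressible without a genome.  ``tss`` must be large
    enough that the resulting coordinates are non-negative.
    """
    lo, hi = sorted((tss + offset_start, tss + offset_end))
    return GenomicInterval(contig, lo, hi)


def merge_regions(regions: RegionSet, max_gap: int = 0) -> RegionSet:
    """Minimal disjoint union of a region set.

    Two intervals merge iff the gap between them is ``<= max_gap``; bookended
    intervals (gap 0) merge at ``max_gap=0``, matching interval-merging at
    maximum feature distance 0.  Strand is ignored.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    merged: list[GenomicInterval] = []
    cur_contig: str | None = None
    cur_start = cur_end = 0
    for iv in regions:
        if iv.contig == cur_contig and iv.start - cur_end <= max_gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_contig is not None:
                merged.append(GenomicInterval(cur_contig, cur_start, cur_end))
            cur_contig, cur_start, cur_end = iv.contig, iv.start, iv.end
    if cur_contig is not None:
        merged.append(GenomicInterval(cur_contig, cur_start, cur_end))
    return RegionSet(merged, regions.genome_tag)


IntersectResult = namedtuple("IntersectResult", ["regions", "overlap_bp"])


def intersect_min_overlap(
    a: RegionSet, b: RegionSet, min_bp: int = 1
) -> IntersectResult:
    """Intervals of ``a`` overlapping the union of ``b`` by at least ``min_bp``.

    Returns the kept sub-set of ``a`` (original records, annotation intact)
    together with the per-kept-interval overlap in bp.  Region sets from
    different assemblies refuse to intersect; translate through the orthology
    module first.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    if a.genome_tag and b.genome_tag and a.genome_tag != b.genome_tag:
        raise ValueError(
            f"genome_tag mismatch: {a.genome_tag!r} vs {b.genome_tag!r}; "
            "map through an orthology chain before intersecting"
        )
    union = merge_regions(b, max_gap=0)
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in union:
        by_contig.setdefault(iv.contig, []).append(iv)
    kept: list[GenomicInterval] = []
    overlaps: list[int] = []
    for iv in a:
        total = 0
        for u in by_contig.get(iv.contig, ()):
            if u.start >= iv.end:
                break
            total += iv.overlap_bp(u)
        if total >= min_bp:
            kept.append(iv)
            overlaps.append(total)
    return IntersectResult(RegionSet(kept, a.genome_tag), overlaps)


# --------------------------------------------------------------------------
# BED / bedGraph I/O


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"malformed BED line {lineno}: {line.rstrip()!r}")
    try:
        contig, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        strand = fields[5] if len(fields) > 5 else "."
        return GenomicInterval(contig, start, end, name=name, score=score, strand=strand)
    except ValueError as exc:
        raise ValueError(f"malformed BED line {lineno}: {exc}") from exc


def read_bed(path, genome_tag: str = "") -> RegionSet:
    """Read BED3/BED6 records; ``track``/``browser``/comment lines skipped."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "browser", "#")):
                continue
            out.append(_parse_bed_line(line, lineno))
    return RegionSet(out, genome_tag)


def write_bed(regions: RegionSet, path) -> None:
    """Write BED6; missing name/score become ``.``/``0``."""
    with open(path, "w") as fh:
        for iv in regions:
            score = 0 if iv.score is None else iv.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t"
                f"{iv.name if iv.name is not None else '.'}\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into a (contig, start, end, value) frame.

    bedGraph forbids overlapping spans; a violation raises with the offending
    contig named.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["contig", "start", "end", "value"],
        dtype={"contig": str},
        skiprows=_count_header_lines(path),
    )
    df = df.sort_values(["contig", "start", "end"], ignore_index=True)
    for contig, grp in df.groupby("contig", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping bedGraph spans on {contig}")
    return df


def _count_header_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(df: pd.DataFrame, path, track_name: str | None = None) -> None:
    with open(path, "w") as fh:
        if track_name:
            fh.write(f"track type=bedGraph name={track_name}\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  columns=["contig", "start", "end", "value"])
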