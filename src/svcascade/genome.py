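"""Core coordinate types: genome layout, intervals, gene models, interval index.

All coordinates inside the package are 0-based half-open ([start, end)).
Conversion to/from 1-based inclusive conventions (GFF3, Bismark cytosine
reports) happens only at file boundaries in :mod:`svcascade.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "GeneModel",
    "IntervalIndex",
    "to_zero_based",
    "to_one_based",
    "merge_intervals",
]


def to_zero_based(pos: int) -> int:
    """Convert a 1-based inclusive position to the internal 0-based convention."""
    return pos - 1


def to_one_based(pos: int) -> int:
    """Inverse of :func:`to_zero_based`."""
    return pos + 1


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class GenomeLayout:
    """Chromosome names and lengths defining the shared coordinate frame."""

    def __init__(self, chromosomes: dict[str, int] | Sequence[tuple[str, int]]):
        items = list(chromosomes.items()) if isinstance(chromosomes, dict) else list(chromosomes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths: dict[str, int] = dict(items)

    @property
    def chromosomes(self) -> dict[str, int]:
        return dict(self._lengths)

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def validate(self, interval: GenomicInterval) -> None:
        """Raise if the interval falls outside the layout."""
        if interval.chrom not in self._lengths:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self._lengths[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"extends beyond chromosome length {self._lengths[interval.chrom]}"
            )


@dataclass
class GeneModel:
    """Gene with strand and exon structure; TSS derived from strand."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if not self.interval.contains(exon):
                raise ValueError(f"exon {exon} outside gene {self.gene_id}")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
            prev_end = exon.end

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def upstream(self, flank: int) -> GenomicInterval | None:
        """Strand-aware upstream flank of width `flank` ending at the TSS."""
        if self.strand == "+":
            start = max(0, self.interval.start - flank)
            end = self.interval.start
        else:
            start = self.interval.end
            end = self.interval.end + flank
        if start >= end:
            return None
        return GenomicInterval(self.interval.chrom, start, end)

    def downstream(self, flank: int) -> GenomicInterval | None:
        """Strand-aware downstream flank of width `flank` after the gene end."""
        if self.strand == "+":
            start = self.interval.end
            end = self.interval.end + flank
        else:
            start = max(0, self.interval.start - flank)
            end = self.interval.start
        if start >= end:
            return None
        return GenomicInterval(self.interval.chrom, start, end)

    def footprint(self, flank: int) -> GenomicInterval:
        """Gene body extended by `flank` bp upstream only (strand-aware)."""
        up = self.upstream(flank)
        if up is None:
            return self.interval
        return GenomicInterval(
            self.interval.chrom,
            min(self.interval.start, up.start),
            max(self.interval.end, up.end),
        )


class IntervalIndex:
    """Overlap index over (interval, payload) pairs, one tree per chromosome."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for interval, payload in items:
            self.add(interval, payload)

    def add(self, interval: GenomicInterval, payload: object) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, payload)

    def query(self, interval: GenomicInterval) -> list[object]:
        """Payloads of all stored intervals overlapping `interval` by >= 1 bp."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]

    def any_overlap(self, interval: GenomicInterval) -> bool:
        tree = self._trees.get(interval.chrom)
        return tree is not None and bool(tree.overlap(interval.start, interval.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out
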