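"""Structural-variant records, type-aware merging, and gene-context annotation.

SV types are INS (insertion), DEL (deletion) and INV (inversion).  Insertions
are anchored on the reference as length-1 intervals [pos, pos+1) carrying the
inserted-sequence length as a payload, so all overlap machinery is uniform.
For methylation carried by the variant sequence itself (InDel-AMR detection)
an InDel exposes :attr:`SVRecord.meth_span`: the deleted interval for DEL,
and [pos, pos+length) for INS — the span the inserted sequence occupies in
the carrier accession's coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .genome import GeneModel, GenomicInterval, IntervalIndex

SV_TYPES = ("INS", "DEL", "INV")
CONTEXT_PRIORITY = ("exon", "intron", "upstream", "downstream", "intergenic")

__all__ = ["SVRecord", "merge_svs", "annotate_sv_context", "SV_TYPES", "CONTEXT_PRIORITY"]


@dataclass(frozen=True)
class SVRecord:
    id: str
    sv_type: str
    interval: GenomicInterval
    length: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.length <= 0:
            raise ValueError(f"SV {self.id}: length must be positive")
        if self.sv_type in ("DEL", "INV") and self.length != self.interval.length:
            raise ValueError(
                f"SV {self.id}: {self.sv_type} length {self.length} != "
                f"interval length {self.interval.length}"
            )
        if self.sv_type == "INS" and self.interval.length != 1:
            raise ValueError(f"SV {self.id}: INS must be anchored as a 1-bp interval")

    @property
    def is_indel(self) -> bool:
        return self.sv_type in ("INS", "DEL")

    @property
    def meth_span(self) -> GenomicInterval:
        """Interval occupied by the variant sequence in the methylome frame
        where that sequence is real (carrier frame for INS)."""
        if self.sv_type == "INS":
            return GenomicInterval(
                self.interval.chrom, self.interval.start, self.interval.start + self.length
            )
        return self.interval


def _cluster_starts(records: list[SVRecord], max_dist: int) -> list[list[SVRecord]]:
    """Single-linkage clustering on start positions (transitive within max_dist)."""
    ordered = sorted(records, key=lambda r: (r.interval.start, r.interval.end, r.id))
    clusters: list[list[SVRecord]] = []
    for rec in ordered:
        if clusters and rec.interval.start - clusters[-1][-1].interval.start <= max_dist:
            clusters[-1].append(rec)
        else:
            clusters.append([rec])
    return clusters


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap_len(b)
    return min(ov / a.length, ov / b.length) if ov else 0.0


def merge_svs(
    callsets: Sequence[Iterable[SVRecord]],
    max_dist: int = 1000,
    inv_reciprocal_overlap: float = 0.5,
) -> list[SVRecord]:
    """Merge SV callsets into a non-redundant set.

    Records of the same type on the same chromosome whose start positions lie
    within ``max_dist`` merge transitively into one representative (leftmost
    start, longest length; sources concatenated).  Inversions additionally
    require reciprocal overlap >= ``inv_reciprocal_overlap`` with the current
    cluster representative, so megabase inversions never absorb unrelated
    small ones merely because their starts are close.
    """
    by_key: dict[tuple[str, str], list[SVRecord]] = {}
    for callset in callsets:
        for rec in callset:
            by_key.setdefault((rec.sv_type, rec.interval.chrom), []).append(rec)

    merged: list[SVRecord] = []
    for (sv_type, _chrom), records in sorted(by_key.items()):
        for cluster in _cluster_starts(records, max_dist):
            if sv_type == "INV":
                subclusters: list[list[SVRecord]] = []
                for rec in cluster:
                    placed = False
                    for sub in subclusters:
                        if _reciprocal_overlap(rec.interval, sub[0].interval) >= inv_reciprocal_overlap:
                            sub.append(rec)
                            placed = True
                            break
                    if not placed:
                        subclusters.append([rec])
            else:
                subclusters = [cluster]
            for sub in subclusters:
                rep = min(sub, key=lambda r: (r.interval.start, -r.length, r.id))
                longest = max(r.length for r in sub)
                sources = ",".join(sorted({r.source for r in sub if r.source}))
                if sv_type == "INS":
                    interval = rep.interval
                else:
                    # DEL/INV invariant ties interval length to SV length
                    interval = GenomicInterval(
                        rep.interval.chrom, rep.interval.start,
                        rep.interval.start + longest,
                    )
                merged.append(replace(rep, length=longest, interval=interval, source=sources))
    merged.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.sv_type, r.id))
    return merged


def annotate_sv_context(
    svs: Iterable[SVRecord],
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> dict[str, str]:
    """Assign each SV one gene-context category with priority
    exon > intron > upstream > downstream > intergenic.

    Upstream/downstream are strand-aware flanks of width ``flank``.  When an
    SV touches several genes, the highest-priority category across all of
    them wins; ties on category are broken by nearest TSS (which only decides
    the attributed gene, not the category).
    """
    index = IntervalIndex()
    for gene in genes:
        if not gene.exons:
            # no exon structure: whole body counts as exonic
            index.add(gene.interval, ("exon", gene))
        else:
            for exon in gene.exons:
                index.add(exon, ("exon", gene))
            index.add(gene.interval, ("intron", gene))
        up = gene.upstream(flank)
        if up is not None:
            index.add(up, ("upstream", gene))
        down = gene.downstream(flank)
        if down is not None:
            index.add(down, ("downstream", gene))

    rank = {cat: i for i, cat in enumerate(CONTEXT_PRIORITY)}
    result: dict[str, str] = {}
    for sv in svs:
        hits = index.query(sv.interval)
        best = "intergenic"
        best_key = (rank["intergenic"], 0)
        for category, gene in hits:
            key = (rank[category], abs(sv.interval.midpoint - gene.tss))
            if key < best_key:
                best, best_key = category, key
        result[sv.id] = best
    return result
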