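"""Genomic intervals and the interval-intersection engine.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
File readers and writers convert at the boundary (GTF is 1-based inclusive,
BED-like tables are already half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in base pairs under half-open semantics (0 if disjoint or
        on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def strands_compatible(self, other: "GenomicInterval") -> bool:
        """Strands match, or either side is unstranded."""
        return self.strand == "." or other.strand == "." or self.strand == other.strand

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between the two intervals' spans; 0 if they overlap.

        Raises ValueError on different chromosomes (the gap is undefined).
        """
        if self.chrom != other.chrom:
            raise ValueError(f"gap undefined across chromosomes {self.chrom}/{other.chrom}")
        if self.overlap_bp(other) > 0:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


def _as_pairs(items) -> list[tuple[str, GenomicInterval]]:
    if isinstance(items, Mapping):
        return list(items.items())
    return [(str(i), iv) for i, iv in items]


def intersect(
    queries: Mapping[str, GenomicInterval] | Iterable[tuple[str, GenomicInterval]],
    subjects: Mapping[str, GenomicInterval] | Iterable[tuple[str, GenomicInterval]],
    stranded: bool = False,
) -> list[tuple[str, str, int]]:
    """All (query_id, subject_id, overlap_bp) pairs with >= 1 bp of overlap.

    Half-open semantics: ``[0,10)`` and ``[10,20)`` do not overlap.  When
    ``stranded`` is true a pair is reported only if the strands match or
    either interval is unstranded.  Output is sorted by (query_id,
    subject_id) so results are reproducible regardless of input order.
    """
    q = _as_pairs(queries)
    s = _as_pairs(subjects)
    trees: dict[str, IntervalTree] = {}
    for sid, iv in s:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (sid, iv))
    out: list[tuple[str, str, int]] = []
    for qid, qiv in q:
        tree = trees.get(qiv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(qiv.start, qiv.end):
            sid, siv = hit.data
            if stranded and not qiv.strands_compatible(siv):
                continue
            out.append((qid, sid, qiv.overlap_bp(siv)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def merge_free_gaps(
    occupied: Sequence[GenomicInterval], chrom: str, chrom_length: int
) -> list[tuple[int, int]]:
    """Maximal gaps on ``chrom`` not covered by any occupied interval.

    Helper for placement logic in the synthetic generator.
    """
    spans = sorted((iv.start, iv.end) for iv in occupied if iv.chrom == chrom)
    gaps = []
    cursor = 0
    for start, end in spans:
        if start > cursor:
            gaps.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < chrom_length:
        gaps.append((cursor, chrom_length))
    return gaps
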