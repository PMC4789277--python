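"""Genomic coordinate primitives.

All coordinates are 0-based half-open ([start, end)), the BED convention,
so interval files round-trip without shifting.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval, optionally stranded.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
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
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> float:
        """Edge-to-edge gap in bp; 0 if overlapping, inf across chromosomes."""
        if self.chrom != other.chrom:
            return float("inf")
        if self.start < other.end and other.start < self.end:
            return 0.0
        return float(max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class ToyGenome:
    """An ordered set of chromosomes with lengths (a chrom-sizes table)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c[1] for c in self.chromosomes)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merge overlapping/touching ones per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
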