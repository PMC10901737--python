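"""Genomic coordinate primitives.

All internal coordinates are 0-based half-open ([start, end)), the BED
convention. Coordinates printed in the genomics literature are usually
1-based fully closed; convert those at the I/O boundary with
:meth:`GenomicInterval.from_one_based_closed`.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a named sequence.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/contig) name.
    start, end : int
        0-based half-open bounds, ``0 <= start <= end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValueError(
                f"invalid interval bounds: start={self.start}, end={self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @classmethod
    def from_one_based_closed(
        cls, chrom: str, start: int, end: int, strand: str = "+"
    ) -> "GenomicInterval":
        """Build from 1-based fully-closed coordinates (as printed in papers)."""
        return cls(chrom, start - 1, end, strand)

    @property
    def width(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.width

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def expanded(self, flank: int) -> "GenomicInterval":
        """Widen by ``flank`` bp on both sides, clipping the start at 0."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        return GenomicInterval(
            self.chrom, max(0, self.start - flank), self.end + flank, self.strand
        )


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals (strand-agnostic)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out
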