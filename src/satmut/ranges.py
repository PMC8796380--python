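"""Genomic coordinate primitives.

All coordinates in this package are 1-based and inclusive at both ends,
matching the targeton parameter file and VCF. Ranges are always expressed
with the start preceding the end regardless of transcript strand; the
conversion to 0-based half-open happens only at the FASTA access boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

PLUS = "+"
MINUS = "-"
STRANDS = (PLUS, MINUS)


@dataclass(frozen=True, order=True)
class GenomicRange:
    """A 1-based inclusive interval on one strand of a chromosome."""

    chromosome: str
    start: int
    end: int
    strand: str = PLUS

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) precedes start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def contains_range(self, other: "GenomicRange") -> bool:
        return (
            other.chromosome == self.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def positions(self) -> range:
        """All positions in the interval, ascending."""
        return range(self.start, self.end + 1)
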