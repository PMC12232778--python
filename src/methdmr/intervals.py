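"""Genomic intervals under a single 0-based half-open convention.

Every coordinate inside the package is 0-based half-open ``[start, end)``;
conversion to the 1-based inclusive style used in printed result tables
happens only in :mod:`methdmr.io_formats` at the writer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name, compared string-exact ("chr" prefix preserved).
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; ``end > start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def format_position(self) -> str:
        """Printed 1-based inclusive position, e.g. ``chr5:180,313,752-180,314,251``.

        The printed width (end - start under 1-based inclusive arithmetic,
        plus one) equals the internal half-open width.
        """
        return f"{self.chrom}:{self.start + 1:,}-{self.end:,}"


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (0-based half-open, no thousands separators)."""
    chrom, _, span = text.replace(",", "").partition(":")
    start_s, _, end_s = span.partition("-")
    return GenomicInterval(chrom, int(start_s), int(end_s))
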