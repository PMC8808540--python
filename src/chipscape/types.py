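"""Core domain types for genomic-interval based ChIP-seq analysis.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED and
narrowPeak convention.  1-based inputs (GTF-style TSS tables) are converted at
the reader boundary so no downstream code ever sees a 1-based coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

CELL_TYPES = ("BC", "LP", "ML", "SC")
CONDITIONS = ("NC", "MUT")
MARKS = ("H3K27ac", "H3K4me3")
ROLES = ("chip", "input")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus summit position and significance.

    ``summit_offset`` is the distance in bp from ``interval.start`` to the
    summit; ``qvalue`` is the FDR-corrected significance from the caller.
    """

    interval: GenomicInterval
    summit_offset: int
    score: float = 0.0
    qvalue: float = 1.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < self.interval.width):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.interval.chrom}:[{self.interval.start},{self.interval.end})"
            )
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue {self.qvalue} not in [0,1]")

    @property
    def summit(self) -> int:
        """Absolute summit coordinate."""
        return self.interval.start + self.summit_offset

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class Genome:
    """Chromosome sizes plus an optional FASTA-backed sequence source."""

    chrom_sizes: dict[str, int]
    fasta_path: Optional[str] = None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def clip(self, iv: GenomicInterval) -> GenomicInterval:
        """Clip an interval to ``[0, chrom length)``."""
        length = self.chrom_sizes[iv.chrom]
        return GenomicInterval(iv.chrom, max(0, iv.start), min(length, iv.end))

    def check(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv} exceeds {iv.chrom} length {self.chrom_sizes[iv.chrom]}"
            )


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: the 5' end of a gene per strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def promoter(self, flank: int = 500) -> GenomicInterval:
        """Promoter window TSS +/- flank, floored at 0."""
        return GenomicInterval(self.chrom, max(0, self.tss - flank), self.tss + flank)


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int


@dataclass(frozen=True)
class SampleMeta:
    """One row of the sample sheet.

    The tuple (cell_type, condition, mark, replicate, role) identifies a
    sample uniquely within a study.
    """

    sample_id: str
    cell_type: str
    condition: str
    mark: str
    replicate: int
    role: str

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.mark not in MARKS:
            raise ValueError(f"mark must be one of {MARKS}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")

    @property
    def group_key(self) -> tuple[str, str, str]:
        """(cell_type, condition, mark) — the experimental group."""
        return (self.cell_type, self.condition, self.mark)


def validate_sample_sheet(samples: Iterable[SampleMeta]) -> None:
    """Raise if two samples share (cell_type, condition, mark, replicate, role)."""
    seen: set[tuple] = set()
    for s in samples:
        key = (s.cell_type, s.condition, s.mark, s.replicate, s.role)
        if key in seen:
            raise ValueError(f"duplicate sample sheet entry {key}")
        seen.add(key)
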