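"""Core genomic types and errors shared across the package.

All coordinates are 0-based, half-open ``[start, end)`` internally.  GTF input
(1-based, inclusive) is converted on ingest; BED and RepeatMasker table starts
are taken as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class AmbiquantError(Exception):
    """Base class for package errors."""


class ParseError(AmbiquantError):
    """A malformed input line or record; message names the location."""


class ConfigurationError(AmbiquantError):
    """Inconsistent user-supplied configuration (e.g. unknown clade label)."""


class SizingError(AmbiquantError):
    """A synthetic genome layout that cannot fit its placements."""


class InputError(AmbiquantError):
    """Semantically invalid input data (e.g. zero-length read)."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval on a named reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Bases shared with ``other``; 0 on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class RepeatCopy:
    """One annotated repeat interval; all copies sharing a name form a group."""

    name: str
    interval: GenomicInterval
    repeat_class: str = "Other"
    repeat_family: str = "Other"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("repeat copy with empty name")


@dataclass(slots=True)
class TEGroup:
    """All repeat copies sharing one name, after same-name merging."""

    name: str
    copies: list[RepeatCopy]
    clade: str | None = None

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    @property
    def total_bp(self) -> int:
        return sum(c.interval.length for c in self.copies)


@dataclass(slots=True)
class CladeTable:
    """Repeat name -> clade labels, with a youngest-to-oldest ordering.

    ``ordering`` ranks every clade label from youngest (index 0) to oldest.
    """

    entries: dict[str, set[str]]
    ordering: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            dupes = sorted({c for c in self.ordering if self.ordering.count(c) > 1})
            raise ConfigurationError(f"duplicate clade labels in ordering: {dupes}")

    def rank(self, label: str) -> int:
        try:
            return self.ordering.index(label)
        except ValueError:
            raise ConfigurationError(
                f"clade label {label!r} missing from the supplied ordering"
            ) from None


#: Default human-lineage clade ordering, youngest first.
DEFAULT_CLADE_ORDERING = [
    "Homo",
    "Homininae",
    "Hominoidea",
    "Catarrhini",
    "Simiiformes",
    "Primates",
    "Euarchontoglires",
    "Eutheria",
    "Theria",
    "Mammalia",
    "Amniota",
    "Tetrapoda",
]


@dataclass(slots=True)
class GeneModel:
    """A gene with a span-based length and exon intervals for overlap.

    Gene length is the genomic span (end - start), *not* the exon sum; read
    overlap, in contrast, is evaluated against the exon union.
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "unknown"

    @property
    def length(self) -> int:
        return self.span.length
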