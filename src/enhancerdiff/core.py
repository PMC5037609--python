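"""Shared genomic data model.

All coordinates are 0-based, half-open ([start, end)) throughout the
package; formats with other conventions (GTF, WIG) are converted at the
I/O boundary and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Input failed a domain invariant (coordinates, ranges, schemas)."""


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned read; strand is mandatory (fragment extension
    is directional)."""

    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError("reads must carry an explicit +/- strand")


@dataclass(frozen=True)
class PeakRecord:
    """A called peak; summit is an absolute bp position when known."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit: Optional[int] = None
    enrichment: Optional[float] = None
    pvalue: Optional[float] = None
    qvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValidationError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene as a single span (union over transcripts) plus its TSS."""

    gene_id: str
    span: GenomicInterval

    @property
    def tss(self) -> int:
        """Transcription start: span.start on +, span.end-1 on -."""
        return self.span.start if self.span.strand == "+" else self.span.end - 1

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id} requires +/- strand")


@dataclass
class ExpressionRecord:
    """Per-gene expression: FPKM per condition plus differential calls.

    ``diff_call_by_pair`` maps an ordered condition pair (A, B) to one of
    ``up_in_A`` / ``up_in_B`` / ``ns`` (strings name the actual conditions).
    """

    gene_id: str
    fpkm_by_condition: dict = field(default_factory=dict)
    diff_call_by_pair: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, fpkm in self.fpkm_by_condition.items():
            if fpkm < 0:
                raise ValidationError(
                    f"gene {self.gene_id}: negative FPKM {fpkm} in {cond}"
                )

    def max_fpkm(self, conditions) -> float:
        vals = [self.fpkm_by_condition.get(c, 0.0) for c in conditions]
        return max(vals) if vals else 0.0
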