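"""Genomic coordinate primitives shared by every pipeline stage.

All internal coordinates are 0-based half-open ``[start, end)``. External
tabular formats (breakpoint tables, interaction tables, ``chrN:start-end``
region strings) are 1-based fully-closed and are converted on read/write by
:mod:`hijackscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class TransInteractionError(ValueError):
    """Raised when a span is requested for a trans (inter-chromosomal) interaction."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name (non-empty; no naming convention enforced).
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        Exclusive end, ``> start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a 0-based point lies inside the interval."""
        return chrom == self.chrom and self.start <= pos < self.end

    def region_string(self) -> str:
        """1-based fully-closed ``chrom:start-end`` notation."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class Breakpoint:
    """One end of a structural variant.

    A two-ended SV record is decomposed into two independent breakpoints
    sharing ``donor_id``; recurrence is counted per breakpoint, not per SV.
    ``pos`` is a 0-based point coordinate.
    """

    donor_id: str
    chrom: str
    pos: int
    sv_type: str | None = None
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if not self.donor_id:
            raise ValueError("donor_id must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class PromoterInteraction:
    """A promoter-capture Hi-C contact: bait (promoter) fragment paired with a
    distal promoter-interacting region (PIR), annotated with the genes of the
    bait promoter and the published interaction score.

    Bait and PIR may sit on different chromosomes (trans contact), but
    span-based operations require a cis contact.
    """

    interaction_id: str
    gene_ids: tuple[str, ...]
    bait: GenomicInterval
    pir: GenomicInterval
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene_ids must be non-empty")
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")
        # allow lists at call sites; store as tuple for hashability
        if not isinstance(self.gene_ids, tuple):
            object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    @property
    def is_cis(self) -> bool:
        return self.bait.chrom == self.pir.chrom


def extend_breakpoint(bp: Breakpoint, flank: int) -> GenomicInterval:
    """Symmetrically flank a breakpoint into an interval of regarded aberration.

    Returns ``[max(0, pos - flank), pos + flank + 1)`` on the breakpoint's
    chromosome: length ``2 * flank + 1`` unless clamped at the contig origin.
    The breakpoint position itself is always contained.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    return GenomicInterval(bp.chrom, max(0, bp.pos - flank), bp.pos + flank + 1)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: touching intervals do not overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def interaction_span(pi: PromoterInteraction) -> GenomicInterval:
    """The full genomic stretch separating (and including) bait and PIR.

    A breakpoint anywhere in this span separates the promoter from its
    interacting region on the rearranged allele. Defined for cis contacts only.
    """
    if not pi.is_cis:
        raise TransInteractionError(
            f"interaction {pi.interaction_id} is trans "
            f"({pi.bait.chrom} vs {pi.pir.chrom}); span is undefined"
        )
    return GenomicInterval(
        pi.bait.chrom,
        min(pi.bait.start, pi.pir.start),
        max(pi.bait.end, pi.pir.end),
    )
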