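"""Core genomic coordinate types.

All internal coordinates are 0-based half-open ``[start, end)``; conversion
to/from the 1-based inclusive convention of GFF3 happens only at the I/O
boundary (:mod:`cisnat.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

STRANDS = (PLUS, MINUS)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval on a chromosome, 0-based half-open.

    ``strand`` is ``"+"``, ``"-"``, or ``"."`` for intervals (such as a pair
    overlap) where strand does not apply.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Width of the intersection with ``other``; 0 when disjoint or on
        different chromosomes (strand is ignored)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Strandless intersection interval, or None when disjoint."""
        if self.overlap_length(other) == 0:
            return None
        return GenomicInterval(
            self.chrom,
            max(self.start, other.start),
            min(self.end, other.end),
            UNSTRANDED,
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True when ``other`` lies fully within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


PROTEIN_CODING = "protein_coding"
OTHER_BIOTYPE = "other"


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene locus.

    ``interval`` is the maximal span over all isoforms, introns included.
    ``biotype`` collapses the annotation's vocabulary to the binary
    distinction the pair scanner needs: ``protein_coding`` or ``other``.
    ``exon_spans`` is populated only in exon-level span mode.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = PROTEIN_CODING
    exon_spans: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.biotype not in (PROTEIN_CODING, OTHER_BIOTYPE):
            raise ValueError(f"invalid biotype {self.biotype!r}")
        if self.interval.strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got "
                f"{self.interval.strand!r}"
            )
        for exon in self.exon_spans:
            if not self.interval.contains(exon) or exon.strand != self.interval.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon {exon} outside gene span or on "
                    "a different strand"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def is_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING

    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3' end (end for +, start for -)."""
        return self.end if self.strand == PLUS else self.start

    def five_prime_end(self) -> int:
        """Genomic coordinate of the 5' end (start for +, end for -)."""
        return self.start if self.strand == PLUS else self.end

    def with_interval(self, interval: GenomicInterval) -> "GeneModel":
        return replace(self, interval=interval, exon_spans=())


def sort_genes(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Deterministic gene ordering: (chrom, start, gene_id)."""
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
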