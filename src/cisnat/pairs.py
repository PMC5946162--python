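"""Candidate cis-NAT pair detection and classification.

A qualifying pair is two protein-coding genes on the same chromosome and
opposite strands whose spans overlap by more than 21 bp (``min_overlap``
defaults to 22, strict reading of the >21 nt rule). Orientation is
classified by the nearest-ends rule: compare the genomic distance between
the two 3' ends against the distance between the two 5' ends; the smaller
distance names the class (tie -> three_prime). For partially overlapping
pairs this coincides with the convergent (tail-to-tail, 3'-3') / divergent
(head-to-head, 5'-5') arrangement; for containment pairs — one span fully
inside the other — it supplies a deterministic convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

from .intervals import GeneModel, GenomicInterval, MINUS, PLUS

MIN_OVERLAP_DEFAULT = 22

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"
ORIENTATION_CLASSES = (THREE_PRIME, FIVE_PRIME)

SOURCE_ANNOTATION = "annotation"
SOURCE_RNASEQ = "rnaseq_extended"


def make_pair_id(gene_a: str, gene_b: str) -> str:
    """Canonical pair identifier: lexicographically sorted ids joined by '|'."""
    a, b = sorted((gene_a, gene_b))
    return f"{a}|{b}"


@dataclass(frozen=True)
class NatPair:
    """A candidate cis-NAT pair. ``gene_a`` < ``gene_b`` lexicographically."""

    pair_id: str
    gene_a: str
    gene_b: str
    overlap: GenomicInterval
    overlap_length: int
    orientation_class: str
    containment: bool
    source: str = SOURCE_ANNOTATION
    triplet_set_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")
        if self.orientation_class not in ORIENTATION_CLASSES:
            raise ValueError(f"bad orientation_class {self.orientation_class!r}")
        if self.source not in (SOURCE_ANNOTATION, SOURCE_RNASEQ):
            raise ValueError(f"bad source {self.source!r}")
        if self.overlap_length != self.overlap.length:
            raise ValueError("overlap_length inconsistent with overlap interval")


@dataclass(frozen=True)
class TripletSet:
    """Three genes where the middle gene antisense-overlaps both neighbors."""

    set_id: str
    gene_ids: Tuple[str, str, str]
    pair_ids: Tuple[str, str]


def classify_orientation(
    gene_a: GeneModel, gene_b: GeneModel
) -> Tuple[str, bool]:
    """Orientation class and containment flag for an antisense pair.

    Returns ``(orientation_class, containment)``. The genes must lie on
    opposite strands of the same chromosome.
    """
    if gene_a.chrom != gene_b.chrom or gene_a.strand == gene_b.strand:
        raise ValueError("orientation is defined for antisense pairs only")
    plus, minus = (gene_a, gene_b) if gene_a.strand == PLUS else (gene_b, gene_a)
    containment = plus.interval.contains(minus.interval) or minus.interval.contains(
        plus.interval
    )
    # plus 3' end = plus.end, minus 3' end = minus.start (and symmetrically 5')
    d3 = abs(plus.end - minus.start)
    d5 = abs(plus.start - minus.end)
    orientation = THREE_PRIME if d3 <= d5 else FIVE_PRIME
    return orientation, containment


def _build_pair(gene_a: GeneModel, gene_b: GeneModel, source: str) -> NatPair:
    overlap = gene_a.interval.intersect(gene_b.interval)
    assert overlap is not None
    orientation, containment = classify_orientation(gene_a, gene_b)
    first, second = sorted((gene_a, gene_b), key=lambda g: g.gene_id)
    return NatPair(
        pair_id=make_pair_id(gene_a.gene_id, gene_b.gene_id),
        gene_a=first.gene_id,
        gene_b=second.gene_id,
        overlap=overlap,
        overlap_length=overlap.length,
        orientation_class=orientation,
        containment=containment,
        source=source,
    )


def _qualifies(a: GeneModel, b: GeneModel, min_overlap: int) -> bool:
    return (
        a.is_coding
        and b.is_coding
        and a.strand != b.strand
        and a.interval.overlap_length(b.interval) >= min_overlap
    )


def find_candidate_pairs(
    genes: Iterable[GeneModel],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    source: str = SOURCE_ANNOTATION,
) -> list[NatPair]:
    """Sweep-line scan for antisense overlapping protein-coding gene pairs.

    Each qualifying unordered pair is returned exactly once, sorted by
    (chrom, overlap start, pair_id). Same-strand overlaps and pairs with a
    non-coding member are excluded.
    """
    by_chrom: Dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    pairs: list[NatPair] = []
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        active: list[GeneModel] = []
        for gene in chrom_genes:
            # retire genes that end before this one starts (cannot overlap
            # it, nor anything later since starts are non-decreasing)
            active = [g for g in active if g.end > gene.start]
            for other in active:
                if _qualifies(gene, other, min_overlap):
                    pairs.append(_build_pair(other, gene, source))
            active.append(gene)
    pairs.sort(key=lambda p: (p.overlap.chrom, p.overlap.start, p.pair_id))
    return pairs


def brute_force_pairs(
    genes: Sequence[GeneModel],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    source: str = SOURCE_ANNOTATION,
) -> list[NatPair]:
    """O(n^2) all-pairs reference scanner (test oracle for the sweep)."""
    genes = list(genes)
    pairs = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if a.chrom == b.chrom and _qualifies(a, b, min_overlap):
                pairs.append(_build_pair(a, b, source))
    pairs.sort(key=lambda p: (p.overlap.chrom, p.overlap.start, p.pair_id))
    return pairs


def find_triplet_sets(pairs: Sequence[NatPair]) -> list[TripletSet]:
    """Group pairs into three-gene overlap sets.

    Every gene participating in exactly two pairs (the middle gene) yields
    one set of it plus its two partners; chains of four or more genes yield
    one set per consecutive triple.
    """
    partners: Dict[str, list[Tuple[str, str]]] = {}
    for pair in pairs:
        partners.setdefault(pair.gene_a, []).append((pair.gene_b, pair.pair_id))
        partners.setdefault(pair.gene_b, []).append((pair.gene_a, pair.pair_id))
    sets = []
    for middle in sorted(partners):
        links = sorted(partners[middle])
        if len(links) != 2:
            continue
        (left, pid_left), (right, pid_right) = links
        sets.append(
            TripletSet(
                set_id=f"triplet:{middle}",
                gene_ids=(left, middle, right),
                pair_ids=(pid_left, pid_right),
            )
        )
    return sets


def annotate_triplets(
    pairs: Sequence[NatPair], triplets: Sequence[TripletSet]
) -> list[NatPair]:
    """Return pairs with ``triplet_set_id`` filled in (comma-joined when a
    pair belongs to two sets, as happens inside longer chains)."""
    membership: Dict[str, list[str]] = {}
    for trip in triplets:
        for pid in trip.pair_ids:
            membership.setdefault(pid, []).append(trip.set_id)
    return [
        replace(p, triplet_set_id=",".join(sorted(membership[p.pair_id])))
        if p.pair_id in membership
        else p
        for p in pairs
    ]
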