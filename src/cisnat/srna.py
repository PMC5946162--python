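"""Small-RNA evidence for cis-NAT pairs.

NAT-derived siRNAs arise from the double-stranded overlap region, so the
decisive evidence for a pair is sRNA reads inside its overlap interval.
Alignments are first filtered to the canonical plant sRNA size window
(21-24 nt by default); a gene "has sRNA" when at least one filtered
alignment overlaps its span by >= 1 bp on either strand; overlap-region
evidence requires, by default, full containment of the read within the
overlap interval (an intersection policy is available). Hit counts are
abundance-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .io import SRNA_COLUMNS
from .pairs import NatPair

LENGTH_RANGE_DEFAULT = (21, 24)

POLICY_CONTAINED = "contained"
POLICY_INTERSECT = "intersect"
OVERLAP_POLICIES = (POLICY_CONTAINED, POLICY_INTERSECT)


@dataclass(frozen=True)
class SrnaAlignment:
    """A mapped small-RNA read (possibly collapsed: ``abundance`` identical
    copies)."""

    interval: GenomicInterval
    read_length: int
    abundance: int = 1

    def __post_init__(self) -> None:
        if self.read_length != self.interval.length:
            raise ValueError("read_length must equal the aligned span width")
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


@dataclass(frozen=True)
class SrnaEvidence:
    pair_id: str
    gene_a_hits: int
    gene_b_hits: int
    overlap_hits: int
    gene_detected_a: bool
    gene_detected_b: bool
    overlap_detected: bool


def srna_from_frame(df: pd.DataFrame) -> list[SrnaAlignment]:
    """Build alignments from a chrom/start/end/strand/length/abundance frame."""
    out = []
    for row in df[SRNA_COLUMNS].itertuples(index=False):
        out.append(
            SrnaAlignment(
                interval=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                read_length=int(row.length),
                abundance=int(row.abundance),
            )
        )
    return out


def filter_srna(
    alignments: Iterable[SrnaAlignment],
    length_range: Tuple[int, int] = LENGTH_RANGE_DEFAULT,
) -> list[SrnaAlignment]:
    """Keep alignments whose read length falls inside ``length_range``
    (inclusive on both ends)."""
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError(f"bad length range {length_range}")
    return [a for a in alignments if lo <= a.read_length <= hi]


def srna_per_gene(
    alignments: Sequence[SrnaAlignment],
    genes: Sequence[GeneModel],
) -> Dict[str, int]:
    """Abundance-weighted sRNA hits per gene (>= 1 bp overlap, either
    strand); a gene is "detected" when its count is >= 1."""
    counts = {g.gene_id: 0 for g in genes}
    for gene in genes:
        for aln in alignments:
            if gene.interval.overlap_length(aln.interval) >= 1:
                counts[gene.gene_id] += aln.abundance
    return counts


def srna_in_overlap(
    pair: NatPair,
    alignments: Sequence[SrnaAlignment],
    policy: str = POLICY_CONTAINED,
) -> Tuple[int, bool]:
    """Hits inside a pair's overlap region and the detection flag.

    ``contained`` (default) counts reads lying fully within the overlap
    interval; ``intersect`` counts any >= 1 bp intersection. Either strand
    qualifies.
    """
    if policy not in OVERLAP_POLICIES:
        raise ValueError(f"policy must be one of {OVERLAP_POLICIES}")
    hits = 0
    for aln in alignments:
        if policy == POLICY_CONTAINED:
            ok = pair.overlap.contains(aln.interval)
        else:
            ok = pair.overlap.overlap_length(aln.interval) >= 1
        if ok:
            hits += aln.abundance
    return hits, hits >= 1


def evidence_for_pairs(
    pairs: Sequence[NatPair],
    alignments: Sequence[SrnaAlignment],
    genes: Sequence[GeneModel],
    policy: str = POLICY_CONTAINED,
) -> Dict[str, SrnaEvidence]:
    """Per-pair sRNA evidence table keyed by pair_id."""
    gene_counts = srna_per_gene(alignments, genes)
    evidence = {}
    for pair in pairs:
        hits_a = gene_counts.get(pair.gene_a, 0)
        hits_b = gene_counts.get(pair.gene_b, 0)
        overlap_hits, detected = srna_in_overlap(pair, alignments, policy)
        evidence[pair.pair_id] = SrnaEvidence(
            pair_id=pair.pair_id,
            gene_a_hits=hits_a,
            gene_b_hits=hits_b,
            overlap_hits=overlap_hits,
            gene_detected_a=hits_a >= 1,
            gene_detected_b=hits_b >= 1,
            overlap_detected=detected,
        )
    return evidence
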