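"""Per-gene expression quantification (RPM) and pair-level expression gates.

A gene is expressed when its reads-per-million is at least 1 (inclusive).
Pairs fall into three categories: both members below the threshold
(``both_low``), exactly one at/above it (``one_expressed``), or both
(``both_expressed``). A read counts toward every gene whose locus span it
overlaps by at least one base (strand-matched in stranded mode); the RPM
denominator is the total number of mapped reads in the library, not the
per-gene sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .intervals import GeneModel
from .io import Alignment
from .pairs import NatPair

logger = logging.getLogger(__name__)

RPM_THRESHOLD_DEFAULT = 1.0

BOTH_LOW = "both_low"
ONE_EXPRESSED = "one_expressed"
BOTH_EXPRESSED = "both_expressed"
UNKNOWN = "unknown"
EXPRESSION_CATEGORIES = (BOTH_LOW, ONE_EXPRESSED, BOTH_EXPRESSED)


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    read_count: int
    rpm: float
    expressed: bool


@dataclass(frozen=True)
class PairExpressionStatus:
    pair_id: str
    category: str


def count_reads_per_gene(
    alignments: Iterable[Alignment],
    genes: Sequence[GeneModel],
    strand_mode: str = "unstranded",
) -> Tuple[Dict[str, int], int]:
    """Count, for every gene, the reads overlapping its span by >= 1 bp.

    A read overlapping several genes is counted for each of them. Returns
    the per-gene counts and the total number of mapped reads in the input.
    """
    if strand_mode not in ("stranded", "unstranded"):
        raise ValueError(f"bad strand_mode {strand_mode!r}")
    trees: Dict[str, IntervalTree] = {}
    counts: Dict[str, int] = {g.gene_id: 0 for g in genes}
    for gene in genes:
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end, (gene.gene_id, gene.strand)
        )
    total = 0
    for aln in alignments:
        total += 1
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(aln.start, aln.end):
            gene_id, gene_strand = hit.data
            if strand_mode == "stranded" and gene_strand != aln.strand:
                continue
            counts[gene_id] += 1
    return counts, total


def compute_rpm(read_count: int, total_mapped_reads: int) -> float:
    """reads-per-million: count x 10^6 / total mapped reads (no pseudocount)."""
    if total_mapped_reads < 1:
        raise ValueError("total_mapped_reads must be >= 1")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count * 1_000_000 / total_mapped_reads


def expression_records(
    counts: Mapping[str, int],
    total_mapped_reads: int,
    rpm_threshold: float = RPM_THRESHOLD_DEFAULT,
) -> Dict[str, ExpressionRecord]:
    records = {}
    for gene_id, count in counts.items():
        rpm = compute_rpm(count, total_mapped_reads)
        records[gene_id] = ExpressionRecord(gene_id, count, rpm, rpm >= rpm_threshold)
    return records


def categorize_pair_expression(
    pair: NatPair,
    records: Mapping[str, ExpressionRecord],
) -> PairExpressionStatus:
    """Expression category of a pair; ``unknown`` when a record is missing."""
    rec_a = records.get(pair.gene_a)
    rec_b = records.get(pair.gene_b)
    if rec_a is None or rec_b is None:
        missing = pair.gene_a if rec_a is None else pair.gene_b
        logger.warning(
            "pair %s: no expression record for %s; excluded from tallies",
            pair.pair_id, missing,
        )
        return PairExpressionStatus(pair.pair_id, UNKNOWN)
    n_expressed = int(rec_a.expressed) + int(rec_b.expressed)
    category = (BOTH_LOW, ONE_EXPRESSED, BOTH_EXPRESSED)[n_expressed]
    return PairExpressionStatus(pair.pair_id, category)
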