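"""End-to-end orchestration: scan, extend, gate, assign, intersect, report.

Stages run in a fixed order: antisense pair scan on the annotation;
boundary extension from RNA-seq coverage and novel-pair detection;
RPM-based expression gating; sperm assignment on the expressed subset,
then vegetative-cell assignment; small-RNA evidence. The result is one
master table with a row per pair, seven category tables projected from it,
and a run summary of the counts surviving each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import coverage as cov
from . import expression as expr
from . import microarray, srna
from .annotation import read_annotation
from .intervals import GeneModel
from .io import read_alignments, read_srna_table
from .pairs import (
    NatPair,
    annotate_triplets,
    find_candidate_pairs,
    find_triplet_sets,
)
from .simulate import NOT_EVALUATED

logger = logging.getLogger(__name__)

MASTER_COLUMNS = [
    "pair_id", "gene_a", "gene_b", "chrom", "overlap_start", "overlap_end",
    "overlap_length", "orientation_class", "containment", "source",
    "triplet_set_id", "read_count_a", "read_count_b", "rpm_a", "rpm_b",
    "expression_category", "sperm_status", "vc_status",
    "srna_gene_a", "srna_gene_b", "srna_overlap_hits", "srna_overlap_detected",
]

CATEGORY_TABLES = {
    "pairs_by_orientation": lambda df: df.sort_values(
        ["orientation_class", "chrom", "overlap_start", "pair_id"], kind="mergesort"
    ),
    "pairs_both_low": lambda df: df[df.expression_category == "both_low"],
    "pairs_expressed": lambda df: df[
        df.expression_category.isin(["one_expressed", "both_expressed"])
    ],
    "pairs_sperm_both": lambda df: df[df.sperm_status == "both"],
    "pairs_sperm_one": lambda df: df[df.sperm_status == "one"],
    "pairs_vc_both": lambda df: df[df.vc_status == "both"],
    "pairs_vc_one": lambda df: df[df.vc_status == "one"],
}


@dataclass
class PipelineConfig:
    """Declarative run configuration; every threshold the method uses is a
    named key with the method's default."""

    annotation: str
    rnaseq: str
    array: str
    srna: Optional[str] = None
    strand_mode: str = "unstranded"
    span_mode: str = "locus"
    min_overlap: int = 22
    rpm_threshold: float = 1.0
    ratio_threshold: float = 3.0
    marginal_as_present: bool = False
    min_depth: int = 2
    max_gap: int = 50
    max_extension: int = 2000
    srna_min_length: int = 21
    srna_max_length: int = 24
    srna_overlap_policy: str = "contained"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as out:
            yaml.safe_dump(dataclasses.asdict(self), out, sort_keys=True)


@dataclass
class PipelineResult:
    """Master pair table, per-gene expression table, and summary counts."""

    master: pd.DataFrame
    expression: pd.DataFrame
    summary: Dict[str, Optional[int]]
    pairs: List[NatPair] = field(default_factory=list, repr=False)
    genes: List[GeneModel] = field(default_factory=list, repr=False)

    def write(self, outdir: str) -> Dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {"master": os.path.join(outdir, "master.tsv")}
        self.master.to_csv(paths["master"], sep="\t", index=False)
        paths["expression"] = os.path.join(outdir, "expression.tsv")
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        paths["pairs"] = os.path.join(outdir, "pairs.tsv")
        bed_like = self.master[
            ["chrom", "overlap_start", "overlap_end", "pair_id",
             "overlap_length", "orientation_class", "containment", "source"]
        ]
        bed_like.to_csv(paths["pairs"], sep="\t", index=False)
        for name, path in write_category_tables(self.master, outdir).items():
            paths[name] = path
        paths["summary"] = os.path.join(outdir, "summary.json")
        with open(paths["summary"], "w") as out:
            json.dump(self.summary, out, indent=1, sort_keys=True)
            out.write("\n")
        return paths


def write_category_tables(master: pd.DataFrame, outdir: str) -> Dict[str, str]:
    """The seven category tables, each a row-subset of the master table."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, select in CATEGORY_TABLES.items():
        path = os.path.join(outdir, f"{name}.tsv")
        select(master).to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> PipelineResult:
    """Execute every stage on the configured inputs.

    Missing input files fail before any stage runs. Gene ids present in the
    pair set but absent from the array table leave the affected pairs with
    unknown cell status.
    """
    required = {"annotation": config.annotation, "rnaseq": config.rnaseq,
                "array": config.array}
    if config.srna is not None:
        required["srna"] = config.srna
    for label, path in required.items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"{label} input not found: {path}")

    genes = read_annotation(config.annotation, span_mode=config.span_mode)
    logger.info("annotation: %d genes", len(genes))

    ann_pairs = find_candidate_pairs(genes, config.min_overlap)
    logger.info("scan: %d annotation pairs", len(ann_pairs))

    alignments = read_alignments(config.rnaseq)
    track = cov.build_coverage(alignments, config.strand_mode)
    observed = cov.extend_all(
        genes, track, config.min_depth, config.max_gap, config.max_extension
    )
    novel = cov.detect_novel_pairs(observed, genes, ann_pairs, config.min_overlap)
    logger.info("extend: %d novel pairs", len(novel))

    pairs = ann_pairs + novel
    triplets = find_triplet_sets(pairs)
    pairs = annotate_triplets(pairs, triplets)
    logger.info("triplets: %d sets", len(triplets))

    counts, total = expr.count_reads_per_gene(alignments, genes, config.strand_mode)
    records = expr.expression_records(counts, max(total, 1), config.rpm_threshold)
    categories = {
        p.pair_id: expr.categorize_pair_expression(p, records).category for p in pairs
    }
    expressed_pairs = [
        p for p in pairs
        if categories[p.pair_id] in (expr.ONE_EXPRESSED, expr.BOTH_EXPRESSED)
    ]
    logger.info(
        "expression gate: %d of %d pairs pass", len(expressed_pairs), len(pairs)
    )

    array_records = microarray.read_array_table(config.array)
    assignments = {
        p.pair_id: microarray.assign_pair(
            p, array_records, config.ratio_threshold, config.marginal_as_present
        )
        for p in expressed_pairs
    }
    logger.info(
        "cell assignment: sperm both=%d, vc both=%d",
        sum(a.sperm_status == "both" for a in assignments.values()),
        sum(a.vc_status == "both" for a in assignments.values()),
    )

    evidence = None
    if config.srna is not None:
        srna_alns = srna.filter_srna(
            srna.srna_from_frame(read_srna_table(config.srna)),
            (config.srna_min_length, config.srna_max_length),
        )
        # gene-level sRNA intersection uses the same extended transcript
        # spans the pair detection used, so overlap evidence (which lies in
        # the intersection of the two spans) always implies gene evidence
        spans = {o.gene_id: o.interval for o in observed}
        extended_genes = [
            g.with_interval(spans[g.gene_id]) if g.gene_id in spans else g
            for g in genes
        ]
        evidence = srna.evidence_for_pairs(
            pairs, srna_alns, extended_genes, config.srna_overlap_policy
        )
        logger.info(
            "sRNA: %d pairs with overlap evidence",
            sum(e.overlap_detected for e in evidence.values()),
        )

    master = _build_master(pairs, records, categories, assignments, evidence)
    expression_table = pd.DataFrame(
        [
            (r.gene_id, r.read_count, r.rpm, r.expressed)
            for r in sorted(records.values(), key=lambda r: r.gene_id)
        ],
        columns=["gene_id", "read_count", "rpm", "expressed"],
    )
    summary = summarize(master, n_triplet_sets=len(triplets))
    result = PipelineResult(
        master=master, expression=expression_table, summary=summary,
        pairs=pairs, genes=genes,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def _build_master(pairs, records, categories, assignments, evidence) -> pd.DataFrame:
    rows = []
    for pair in pairs:
        rec_a = records.get(pair.gene_a)
        rec_b = records.get(pair.gene_b)
        assignment = assignments.get(pair.pair_id)
        row = {
            "pair_id": pair.pair_id,
            "gene_a": pair.gene_a,
            "gene_b": pair.gene_b,
            "chrom": pair.overlap.chrom,
            "overlap_start": pair.overlap.start,
            "overlap_end": pair.overlap.end,
            "overlap_length": pair.overlap_length,
            "orientation_class": pair.orientation_class,
            "containment": pair.containment,
            "source": pair.source,
            "triplet_set_id": pair.triplet_set_id or "",
            "read_count_a": rec_a.read_count if rec_a else pd.NA,
            "read_count_b": rec_b.read_count if rec_b else pd.NA,
            "rpm_a": rec_a.rpm if rec_a else pd.NA,
            "rpm_b": rec_b.rpm if rec_b else pd.NA,
            "expression_category": categories[pair.pair_id],
            "sperm_status": assignment.sperm_status if assignment else NOT_EVALUATED,
            "vc_status": assignment.vc_status if assignment else NOT_EVALUATED,
        }
        if evidence is not None:
            ev = evidence[pair.pair_id]
            row.update(
                srna_gene_a=ev.gene_detected_a,
                srna_gene_b=ev.gene_detected_b,
                srna_overlap_hits=ev.overlap_hits,
                srna_overlap_detected=ev.overlap_detected,
            )
        else:
            row.update(
                srna_gene_a=NOT_EVALUATED,
                srna_gene_b=NOT_EVALUATED,
                srna_overlap_hits=pd.NA,
                srna_overlap_detected=NOT_EVALUATED,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=MASTER_COLUMNS)


def summarize(master: pd.DataFrame, n_triplet_sets: int) -> Dict[str, Optional[int]]:
    """Stage-by-stage counts; sRNA entries are None when not evaluated."""
    has_srna = (
        len(master) == 0 or master["srna_overlap_detected"].iloc[0] != NOT_EVALUATED
    )
    genes_with_srna = None
    pairs_with_srna = None
    pairs_overlap = None
    if has_srna and len(master):
        detected_genes = set(master.loc[master.srna_gene_a == True, "gene_a"]) | set(  # noqa: E712
            master.loc[master.srna_gene_b == True, "gene_b"]  # noqa: E712
        )
        genes_with_srna = len(detected_genes)
        pairs_with_srna = int(
            ((master.srna_gene_a == True) | (master.srna_gene_b == True)).sum()  # noqa: E712
        )
        pairs_overlap = int((master.srna_overlap_detected == True).sum())  # noqa: E712
    elif has_srna:
        genes_with_srna = pairs_with_srna = pairs_overlap = 0
    return {
        "pairs_total": int(len(master)),
        "pairs_three_prime": int((master.orientation_class == "three_prime").sum()),
        "pairs_five_prime": int((master.orientation_class == "five_prime").sum()),
        "pairs_containment": int(master.containment.sum()),
        "triplet_sets": int(n_triplet_sets),
        "pairs_novel": int((master.source == "rnaseq_extended").sum()),
        "pairs_both_low": int((master.expression_category == "both_low").sum()),
        "pairs_expressed": int(
            master.expression_category.isin(["one_expressed", "both_expressed"]).sum()
        ),
        "pairs_sperm_both": int((master.sperm_status == "both").sum()),
        "pairs_sperm_one": int((master.sperm_status == "one").sum()),
        "pairs_vc_both": int((master.vc_status == "both").sum()),
        "pairs_vc_one": int((master.vc_status == "one").sum()),
        "genes_with_srna": genes_with_srna,
        "pairs_with_srna": pairs_with_srna,
        "pairs_overlap_srna": pairs_overlap,
    }
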