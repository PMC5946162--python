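"""Synthetic pollen datasets with planted ground truth.

Generates, from one seeded configuration, the four inputs the pipeline
consumes — a GFF3 annotation, an RNA-seq alignment table, a pollen/sperm
microarray call table, and a small-RNA alignment table — together with a
manifest of everything planted: the true pair set with orientation classes
and containment flags, annotation truncations that create "novel" pairs
recoverable only through boundary extension, per-gene expression designs,
per-pair cell patterns, and sRNA reads placed inside or outside overlap
regions. Negative controls (same-strand overlaps, non-coding partners,
sub-threshold overlaps, out-of-window sRNA lengths) are planted so every
detection criterion has a failing case.

The default configuration is noise-free: read counts are deterministic and
read starts are tiled evenly over the true transcript span, which makes
pipeline recovery of the ground truth exact for any seed. Poisson counts
with uniform placement are available via ``noise_free=False``. Reads carry
their gene's strand; the emitted dataset is meant to be analysed in
stranded mode (see the packaged methods note for why).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import write_annotation
from .intervals import (
    GeneModel,
    GenomicInterval,
    MINUS,
    OTHER_BIOTYPE,
    PLUS,
    PROTEIN_CODING,
)
from .io import ALIGNMENT_COLUMNS, SRNA_COLUMNS, Alignment
from .pairs import (
    FIVE_PRIME,
    SOURCE_ANNOTATION,
    SOURCE_RNASEQ,
    THREE_PRIME,
    brute_force_pairs,
    classify_orientation,
    make_pair_id,
)

EXPRESSION_CYCLE = ("both_expressed", "one_expressed", "both_low")
CELL_PATTERNS = ("sperm_only", "vc_only", "both_cells", "silent")
#: per-pair (pattern_a, pattern_b) combinations cycled over evaluated pairs
CELL_CYCLE = (
    ("sperm_only", "sperm_only"),
    ("vc_only", "vc_only"),
    ("sperm_only", "vc_only"),
    ("both_cells", "silent"),
    ("silent", "silent"),
    ("vc_only", "silent"),
)
SRNA_CYCLE = ("in_overlap", "outside_overlap", "none")

NOT_EVALUATED = "not_evaluated"


class SimulationError(RuntimeError):
    """Planted geometry failed its internal consistency check."""


@dataclass
class SimulationConfig:
    """Knobs for one synthetic dataset; a fixed seed gives byte-identical
    outputs."""

    seed: int = 0
    chrom: str = "Chr1"
    # planted pair counts
    n_three_prime: int = 20
    n_five_prime: int = 5
    n_containment: int = 3
    n_triplet_sets: int = 2
    n_novel: int = 5
    # negative controls
    n_decoy_same_strand: int = 5
    n_decoy_noncoding: int = 5
    n_subthreshold_overlap: int = 5
    plant_length_decoys: bool = True
    # RNA-seq
    read_length: int = 75
    library_size: int = 100_000
    background_reads: int = 0
    noise_free: bool = True
    rpm_expressed_range: Tuple[float, float] = (300.0, 800.0)
    rpm_low_range: Tuple[float, float] = (0.0, 3.0)
    # microarray
    n_array_missing_pairs: int = 1
    signal_high: float = 500.0
    signal_low: float = 20.0
    signal_sigma: float = 0.3
    # geometry
    min_overlap: int = 22
    intergenic_gap: Tuple[int, int] = (200, 400)
    gene_length: Tuple[int, int] = (800, 1600)

    def __post_init__(self) -> None:
        for name in (
            "n_three_prime", "n_five_prime", "n_containment", "n_triplet_sets",
            "n_novel", "n_decoy_same_strand", "n_decoy_noncoding",
            "n_subthreshold_overlap", "background_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthGene:
    gene_id: str
    strand: str
    biotype: str
    true_start: int
    true_end: int
    ann_start: int
    ann_end: int
    target_rpm: float = 0.0
    read_count: int = 0
    cell_pattern: Optional[str] = None
    in_array: bool = True
    expressed: Optional[bool] = None  # realized, filled after read emission


@dataclass
class TruthPair:
    pair_id: str
    gene_a: str
    gene_b: str
    kind: str
    orientation_class: str
    containment: bool
    source: str
    expression_category: Optional[str] = None
    sperm_status: Optional[str] = None
    vc_status: Optional[str] = None
    srna_design: str = "none"
    gene_detected_a: bool = False
    gene_detected_b: bool = False
    overlap_detected: bool = False


@dataclass
class GroundTruth:
    """Planted truth, internally consistent with the emitted files."""

    genes: Dict[str, TruthGene]
    pairs: Dict[str, TruthPair]
    triplet_sets: List[Tuple[str, str]]  # (pair_id, pair_id) per set
    decoy_gene_ids: List[str]
    total_mapped_reads: int = 0

    def tallies(self) -> Dict[str, int]:
        """Expected pipeline run-summary counts."""
        pairs = list(self.pairs.values())
        evaluated = [
            p for p in pairs
            if p.expression_category in ("one_expressed", "both_expressed")
        ]
        gene_srna: set = set()
        for p in pairs:
            if p.gene_detected_a:
                gene_srna.add(p.gene_a)
            if p.gene_detected_b:
                gene_srna.add(p.gene_b)
        return {
            "pairs_total": len(pairs),
            "pairs_three_prime": sum(
                p.orientation_class == THREE_PRIME for p in pairs
            ),
            "pairs_five_prime": sum(
                p.orientation_class == FIVE_PRIME for p in pairs
            ),
            "pairs_containment": sum(p.containment for p in pairs),
            "triplet_sets": len(self.triplet_sets),
            "pairs_novel": sum(p.source == SOURCE_RNASEQ for p in pairs),
            "pairs_both_low": sum(
                p.expression_category == "both_low" for p in pairs
            ),
            "pairs_expressed": len(evaluated),
            "pairs_sperm_both": sum(p.sperm_status == "both" for p in evaluated),
            "pairs_sperm_one": sum(p.sperm_status == "one" for p in evaluated),
            "pairs_vc_both": sum(p.vc_status == "both" for p in evaluated),
            "pairs_vc_one": sum(p.vc_status == "one" for p in evaluated),
            "genes_with_srna": len(gene_srna),
            "pairs_with_srna": sum(
                p.gene_detected_a or p.gene_detected_b for p in pairs
            ),
            "pairs_overlap_srna": sum(p.overlap_detected for p in pairs),
        }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: List[GeneModel]  # annotated models, as the GFF3 records them
    rnaseq: pd.DataFrame
    array: pd.DataFrame
    srna: pd.DataFrame
    truth: GroundTruth

    def alignments(self) -> List[Alignment]:
        return [
            Alignment(str(r.chrom), int(r.start), int(r.end), str(r.strand))
            for r in self.rnaseq.itertuples(index=False)
        ]

    def write(self, outdir: str) -> Dict[str, str]:
        """Write all four inputs plus the truth manifest; returns paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "annotation": os.path.join(outdir, "annotation.gff3"),
            "rnaseq": os.path.join(outdir, "rnaseq.tsv"),
            "array": os.path.join(outdir, "array.tsv"),
            "srna": os.path.join(outdir, "srna.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        write_annotation(self.genes, paths["annotation"])
        self.rnaseq.to_csv(paths["rnaseq"], sep="\t", index=False)
        self.array.to_csv(paths["array"], sep="\t", index=False)
        self.srna.to_csv(paths["srna"], sep="\t", index=False)
        with open(paths["truth"], "w") as out:
            json.dump(truth_to_dict(self.truth), out, indent=1, sort_keys=True)
            out.write("\n")
        return paths


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "genes": {k: dataclasses.asdict(v) for k, v in sorted(truth.genes.items())},
        "pairs": {k: dataclasses.asdict(v) for k, v in sorted(truth.pairs.items())},
        "triplet_sets": [list(t) for t in truth.triplet_sets],
        "decoy_gene_ids": list(truth.decoy_gene_ids),
        "total_mapped_reads": truth.total_mapped_reads,
        "tallies": truth.tallies(),
    }


# ---------------------------------------------------------------------------
# geometry planting

class _Layout:
    """Sequential placement of gene units along one chromosome."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.cursor = 1000
        self.genes: List[TruthGene] = []
        self.pairs: List[TruthPair] = []
        self.triplets: List[Tuple[str, str]] = []
        self.decoys: List[str] = []
        self._gene_no = 0

    def _next_id(self) -> str:
        self._gene_no += 1
        return f"SG{self._gene_no:04d}"

    def _gap(self) -> int:
        lo, hi = self.config.intergenic_gap
        return int(self.rng.integers(lo, hi + 1))

    def _len(self) -> int:
        lo, hi = self.config.gene_length
        return int(self.rng.integers(lo, hi + 1))

    def _add_gene(
        self,
        strand: str,
        true_start: int,
        true_end: int,
        biotype: str = PROTEIN_CODING,
        ann_start: Optional[int] = None,
        ann_end: Optional[int] = None,
    ) -> TruthGene:
        gene = TruthGene(
            gene_id=self._next_id(),
            strand=strand,
            biotype=biotype,
            true_start=true_start,
            true_end=true_end,
            ann_start=true_start if ann_start is None else ann_start,
            ann_end=true_end if ann_end is None else ann_end,
        )
        self.genes.append(gene)
        return gene

    def _add_pair(self, a: TruthGene, b: TruthGene, kind: str, source: str) -> TruthPair:
        model_a = GeneModel(a.gene_id, GenomicInterval(
            self.config.chrom, a.true_start, a.true_end, a.strand))
        model_b = GeneModel(b.gene_id, GenomicInterval(
            self.config.chrom, b.true_start, b.true_end, b.strand))
        orientation, containment = classify_orientation(model_a, model_b)
        first, second = sorted((a, b), key=lambda g: g.gene_id)
        pair = TruthPair(
            pair_id=make_pair_id(a.gene_id, b.gene_id),
            gene_a=first.gene_id,
            gene_b=second.gene_id,
            kind=kind,
            orientation_class=orientation,
            containment=containment,
            source=source,
        )
        self.pairs.append(pair)
        return pair

    # -- unit builders ------------------------------------------------------

    def plant_tail_to_tail(self) -> None:
        la, lb = self._len(), self._len()
        ov = int(self.rng.integers(40, 201))
        a = self._add_gene(PLUS, self.cursor, self.cursor + la)
        b = self._add_gene(MINUS, a.true_end - ov, a.true_end - ov + lb)
        self._add_pair(a, b, "three_prime", SOURCE_ANNOTATION)
        self.cursor = b.true_end + self._gap()

    def plant_head_to_head(self) -> None:
        la, lb = self._len(), self._len()
        ov = int(self.rng.integers(40, 201))
        a = self._add_gene(MINUS, self.cursor, self.cursor + la)
        b = self._add_gene(PLUS, a.true_end - ov, a.true_end - ov + lb)
        self._add_pair(a, b, "five_prime", SOURCE_ANNOTATION)
        self.cursor = b.true_end + self._gap()

    def plant_containment(self, want_three_prime: bool) -> None:
        lo = int(self.rng.integers(2200, 3000))
        li = int(self.rng.integers(300, 600))
        margin = int(self.rng.integers(30, 80))
        outer = self._add_gene(PLUS, self.cursor, self.cursor + lo)
        if want_three_prime:  # inner near the outer (+) gene's 3' end
            inner_end = outer.true_end - margin
            inner = self._add_gene(MINUS, inner_end - li, inner_end)
        else:  # inner near the outer gene's 5' end
            inner_start = outer.true_start + margin
            inner = self._add_gene(MINUS, inner_start, inner_start + li)
        pair = self._add_pair(outer, inner, "containment", SOURCE_ANNOTATION)
        want = THREE_PRIME if want_three_prime else FIVE_PRIME
        if pair.orientation_class != want or not pair.containment:
            raise SimulationError("containment unit got an unplanned class")
        self.cursor = outer.true_end + self._gap()

    def plant_triplet(self) -> None:
        la = self._len()
        ov1 = int(self.rng.integers(40, 150))
        ov2 = int(self.rng.integers(40, 150))
        lb = ov1 + ov2 + int(self.rng.integers(300, 700))
        lc = self._len()
        a = self._add_gene(PLUS, self.cursor, self.cursor + la)
        b = self._add_gene(MINUS, a.true_end - ov1, a.true_end - ov1 + lb)
        c = self._add_gene(PLUS, b.true_end - ov2, b.true_end - ov2 + lc)
        p1 = self._add_pair(a, b, "triplet_three_prime", SOURCE_ANNOTATION)
        p2 = self._add_pair(b, c, "triplet_five_prime", SOURCE_ANNOTATION)
        self.triplets.append((p1.pair_id, p2.pair_id))
        self.cursor = c.true_end + self._gap()

    def plant_novel(self) -> None:
        """True transcripts overlap tail-to-tail; annotated spans are
        truncated so they do not overlap at all."""
        la, lb = self._len(), self._len()
        ov = int(self.rng.integers(150, 251))
        gap_ann = int(self.rng.integers(10, 31))
        trunc_a = (ov + gap_ann) // 2
        trunc_b = ov + gap_ann - trunc_a
        a_start = self.cursor
        a_end = a_start + la
        b_start = a_end - ov
        b_end = b_start + lb
        a = self._add_gene(PLUS, a_start, a_end, ann_end=a_end - trunc_a)
        b = self._add_gene(MINUS, b_start, b_end, ann_start=b_start + trunc_b)
        self._add_pair(a, b, "novel_three_prime", SOURCE_RNASEQ)
        self.cursor = b_end + self._gap()

    def plant_decoy_same_strand(self) -> None:
        la, lb = self._len(), self._len()
        ov = int(self.rng.integers(60, 200))
        a = self._add_gene(PLUS, self.cursor, self.cursor + la)
        b = self._add_gene(PLUS, a.true_end - ov, a.true_end - ov + lb)
        self.decoys += [a.gene_id, b.gene_id]
        self.cursor = b.true_end + self._gap()

    def plant_decoy_noncoding(self) -> None:
        la, lb = self._len(), self._len()
        ov = int(self.rng.integers(60, 200))
        a = self._add_gene(PLUS, self.cursor, self.cursor + la)
        b = self._add_gene(
            MINUS, a.true_end - ov, a.true_end - ov + lb, biotype=OTHER_BIOTYPE
        )
        self.decoys += [a.gene_id, b.gene_id]
        self.cursor = b.true_end + self._gap()

    def plant_subthreshold(self, exact_boundary: bool) -> None:
        la, lb = self._len(), self._len()
        # one unit sits exactly at the 21-bp boundary the >21 nt rule rejects
        ov = 21 if exact_boundary else int(self.rng.integers(5, 22))
        a = self._add_gene(PLUS, self.cursor, self.cursor + la)
        b = self._add_gene(MINUS, a.true_end - ov, a.true_end - ov + lb)
        self.decoys += [a.gene_id, b.gene_id]
        self.cursor = b.true_end + self._gap()


def _plant_layout(config: SimulationConfig, rng: np.random.Generator) -> _Layout:
    layout = _Layout(config, rng)
    for _ in range(config.n_three_prime):
        layout.plant_tail_to_tail()
    for _ in range(config.n_five_prime):
        layout.plant_head_to_head()
    for i in range(config.n_containment):
        layout.plant_containment(want_three_prime=(i % 2 == 0))
    for _ in range(config.n_triplet_sets):
        layout.plant_triplet()
    for _ in range(config.n_novel):
        layout.plant_novel()
    for _ in range(config.n_decoy_same_strand):
        layout.plant_decoy_same_strand()
    for _ in range(config.n_decoy_noncoding):
        layout.plant_decoy_noncoding()
    for i in range(config.n_subthreshold_overlap):
        layout.plant_subthreshold(exact_boundary=(i == 0))
    return layout


def _gene_models(layout: _Layout, config: SimulationConfig, annotated: bool) -> List[GeneModel]:
    out = []
    for g in layout.genes:
        start = g.ann_start if annotated else g.true_start
        end = g.ann_end if annotated else g.true_end
        out.append(
            GeneModel(g.gene_id, GenomicInterval(config.chrom, start, end, g.strand), g.biotype)
        )
    return out


def _verify_layout(layout: _Layout, config: SimulationConfig) -> None:
    """Brute-force oracle check: annotated spans yield exactly the planted
    annotation pairs; true spans yield those plus the planted novel pairs."""
    want_ann = {
        p.pair_id: (p.orientation_class, p.containment)
        for p in layout.pairs
        if p.source == SOURCE_ANNOTATION
    }
    got_ann = {
        p.pair_id: (p.orientation_class, p.containment)
        for p in brute_force_pairs(_gene_models(layout, config, annotated=True), config.min_overlap)
    }
    if got_ann != want_ann:
        raise SimulationError("annotated geometry does not match the planted pair set")
    want_all = {
        p.pair_id: (p.orientation_class, p.containment) for p in layout.pairs
    }
    got_all = {
        p.pair_id: (p.orientation_class, p.containment)
        for p in brute_force_pairs(_gene_models(layout, config, annotated=False), config.min_overlap)
    }
    if got_all != want_all:
        raise SimulationError("true-span geometry does not match the planted pair set")


# ---------------------------------------------------------------------------
# expression / cells / sRNA design

def _design_expression(layout: _Layout, config: SimulationConfig, rng: np.random.Generator) -> None:
    flags: Dict[str, bool] = {}

    def want(gene: TruthGene, expressed: bool) -> None:
        flags.setdefault(gene.gene_id, expressed)

    by_id = {g.gene_id: g for g in layout.genes}
    cycle_i = 0
    for pair in layout.pairs:
        a, b = by_id[pair.gene_a], by_id[pair.gene_b]
        if pair.source == SOURCE_RNASEQ:
            # novel pairs need boundary-extension signal on both genes
            want(a, True)
            want(b, True)
            continue
        category = EXPRESSION_CYCLE[cycle_i % len(EXPRESSION_CYCLE)]
        cycle_i += 1
        if category == "both_expressed":
            want(a, True); want(b, True)
        elif category == "one_expressed":
            want(a, True); want(b, False)
        else:
            want(a, False); want(b, False)
    for gene in layout.genes:  # decoys and any leftovers: expressed
        flags.setdefault(gene.gene_id, True)
    for gene in layout.genes:
        lo, hi = (
            config.rpm_expressed_range if flags[gene.gene_id] else config.rpm_low_range
        )
        gene.target_rpm = float(rng.uniform(lo, hi))


def _design_cells(layout: _Layout, config: SimulationConfig, rng: np.random.Generator) -> None:
    by_id = {g.gene_id: g for g in layout.genes}
    cycle_i = 0
    for pair in layout.pairs:
        combo = CELL_CYCLE[cycle_i % len(CELL_CYCLE)]
        cycle_i += 1
        for gene_id, pattern in zip((pair.gene_a, pair.gene_b), combo):
            gene = by_id[gene_id]
            if gene.cell_pattern is None:
                gene.cell_pattern = pattern
    for gene in layout.genes:
        if gene.cell_pattern is None:
            gene.cell_pattern = CELL_PATTERNS[int(rng.integers(0, len(CELL_PATTERNS)))]
    # drop genes from the array table to plant unknown assignments
    dropped = 0
    for pair in layout.pairs:
        if dropped >= config.n_array_missing_pairs:
            break
        if pair.kind == "three_prime":
            by_id[pair.gene_b].in_array = False
            dropped += 1


def _sperm_flag(pattern: str) -> bool:
    return pattern in ("sperm_only", "both_cells")


def _vc_flag(pattern: str) -> bool:
    return pattern == "vc_only"


# ---------------------------------------------------------------------------
# read emission

def _tile_positions(start: int, end: int, n: int, read_length: int) -> np.ndarray:
    """Evenly spaced read starts covering [start, end) with n reads."""
    hi = max(start, end - read_length)
    if n == 1:
        return np.array([(start + hi) // 2], dtype=np.int64)
    return np.linspace(start, hi, n).round().astype(np.int64)


def _min_tiling_reads(length: int, read_length: int) -> int:
    # spacing <= read_length/2 guarantees depth >= 2 at every covered base
    return int(math.ceil(2 * length / read_length)) + 2


def _emit_rnaseq(
    layout: _Layout, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    novel_genes = {
        gid
        for p in layout.pairs
        if p.source == SOURCE_RNASEQ
        for gid in (p.gene_a, p.gene_b)
    }
    for gene in layout.genes:
        mean = gene.target_rpm * config.library_size / 1e6
        count = int(round(mean)) if config.noise_free else int(rng.poisson(mean))
        if gene.gene_id in novel_genes and count > 0:
            count = max(
                count,
                _min_tiling_reads(gene.true_end - gene.true_start, config.read_length),
            )
        gene.read_count = count
        if count == 0:
            continue
        if config.noise_free:
            starts = _tile_positions(
                gene.true_start, gene.true_end, count, config.read_length
            )
        else:
            hi = max(gene.true_start + 1, gene.true_end - config.read_length)
            starts = rng.integers(gene.true_start, hi, size=count)
        for s in starts:
            s = int(s)
            rows.append(
                (config.chrom, s, min(s + config.read_length, gene.true_end), gene.strand)
            )
    # background: sparse reads in intergenic space, alternating strand
    if config.background_reads:
        chrom_end = max(g.true_end for g in layout.genes) + 500
        spans = sorted((g.true_start, g.true_end) for g in layout.genes)
        for i in range(config.background_reads):
            pos = int(rng.integers(0, chrom_end))
            strand = PLUS if i % 2 == 0 else MINUS
            rows.append((config.chrom, pos, pos + config.read_length, strand))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort").reset_index(drop=True)


def _realize_expression(layout: _Layout, config: SimulationConfig, rnaseq: pd.DataFrame) -> None:
    """Fill realized per-gene expressed flags and per-pair categories by a
    naive scan of the emitted reads against the annotated spans."""
    total = len(rnaseq)
    starts = rnaseq["start"].to_numpy()
    ends = rnaseq["end"].to_numpy()
    strands = rnaseq["strand"].to_numpy()
    for gene in layout.genes:
        hit = (
            (starts < gene.ann_end)
            & (ends > gene.ann_start)
            & (strands == gene.strand)
        )
        count = int(hit.sum())
        rpm = count * 1e6 / total if total else 0.0
        gene.expressed = rpm >= 1.0
    by_id = {g.gene_id: g for g in layout.genes}
    for pair in layout.pairs:
        n = int(by_id[pair.gene_a].expressed) + int(by_id[pair.gene_b].expressed)
        pair.expression_category = ("both_low", "one_expressed", "both_expressed")[n]
        if config.noise_free and pair.expression_category == "both_low" and (
            by_id[pair.gene_a].target_rpm >= 10 or by_id[pair.gene_b].target_rpm >= 10
        ):
            raise SimulationError("noise-free expression design not realized")


def _realize_cells(layout: _Layout) -> None:
    by_id = {g.gene_id: g for g in layout.genes}
    for pair in layout.pairs:
        if pair.expression_category == "both_low":
            pair.sperm_status = NOT_EVALUATED
            pair.vc_status = NOT_EVALUATED
            continue
        a, b = by_id[pair.gene_a], by_id[pair.gene_b]
        if not (a.in_array and b.in_array):
            pair.sperm_status = "unknown"
            pair.vc_status = "unknown"
            continue
        n_sperm = int(_sperm_flag(a.cell_pattern)) + int(_sperm_flag(b.cell_pattern))
        n_vc = int(_vc_flag(a.cell_pattern)) + int(_vc_flag(b.cell_pattern))
        pair.sperm_status = ("neither", "one", "both")[n_sperm]
        pair.vc_status = ("neither", "one", "both")[n_vc]


def _emit_array(
    layout: _Layout, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for gene in layout.genes:
        if not gene.in_array:
            continue
        high = config.signal_high
        low = config.signal_low
        sigma = config.signal_sigma
        pattern = gene.cell_pattern

        def lognorm(mean: float) -> float:
            return float(mean * rng.lognormal(0.0, sigma))

        if pattern == "sperm_only":
            sperm_signal = lognorm(high)
            # keep the pollen/sperm ratio safely below the threshold
            pollen_signal = sperm_signal * float(rng.uniform(0.5, 2.5))
            pollen_call, sperm_call = "P", "P"
        elif pattern == "vc_only":
            pollen_signal = lognorm(high)
            sperm_signal = lognorm(low)
            pollen_call, sperm_call = "P", "A"
        elif pattern == "both_cells":
            sperm_signal = lognorm(high)
            pollen_signal = sperm_signal * float(rng.uniform(0.5, 2.5))
            pollen_call, sperm_call = "P", "P"
        else:  # silent
            pollen_signal = lognorm(low)
            sperm_signal = lognorm(low)
            pollen_call, sperm_call = "A", "A"
        rows.append(
            (
                gene.gene_id,
                round(pollen_signal, 3),
                pollen_call,
                round(sperm_signal, 3),
                sperm_call,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "pollen_signal", "pollen_call", "sperm_signal", "sperm_call"],
    )


def _emit_srna(
    layout: _Layout, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    by_id = {g.gene_id: g for g in layout.genes}
    # every planted true overlap is a forbidden zone for "outside" reads
    forbidden = []
    for pair in layout.pairs:
        a, b = by_id[pair.gene_a], by_id[pair.gene_b]
        forbidden.append(
            (max(a.true_start, b.true_start), min(a.true_end, b.true_end))
        )
    cycle_i = 0
    none_pairs_seen = 0
    for pair in layout.pairs:
        design = SRNA_CYCLE[cycle_i % len(SRNA_CYCLE)]
        cycle_i += 1
        pair.srna_design = design
        a, b = by_id[pair.gene_a], by_id[pair.gene_b]
        ov_start = max(a.true_start, b.true_start)
        ov_end = min(a.true_end, b.true_end)
        if design == "in_overlap":
            # centered in the true overlap so the read stays inside the
            # (possibly slightly narrower) extension-derived overlap too
            center = (ov_start + ov_end) // 2
            for k in range(2):
                length = int(rng.integers(21, 25))
                start = center - length // 2 + (k - 1) * 3
                strand = PLUS if k % 2 == 0 else MINUS
                rows.append(
                    (config.chrom, start, start + length, strand, length,
                     int(rng.integers(1, 6)))
                )
        elif design == "outside_overlap":
            # inside whichever gene has room to the left of the overlap,
            # clear of every planted overlap region
            host = a if a.true_start < ov_start else b
            lo, hi = host.true_start, ov_start - 5
            for f_start, f_end in forbidden:
                if f_start < hi and f_end > lo and f_end < hi:
                    lo = max(lo, f_end + 5)
            length = int(rng.integers(21, 25))
            if hi - length <= lo:
                raise SimulationError("no room for an outside-overlap sRNA read")
            start = int(rng.integers(lo, hi - length))
            strand = PLUS if cycle_i % 2 == 0 else MINUS
            rows.append(
                (config.chrom, start, start + length, strand, length,
                 int(rng.integers(1, 6)))
            )
        else:
            # out-of-window length decoys inside the first "none" overlaps
            if config.plant_length_decoys and none_pairs_seen < 2:
                length = 19 if none_pairs_seen == 0 else 30
                center = (ov_start + ov_end) // 2
                start = center - length // 2
                rows.append(
                    (config.chrom, start, start + length, PLUS, length, 1)
                )
            none_pairs_seen += 1
    return pd.DataFrame(rows, columns=SRNA_COLUMNS)


def _realize_srna(layout: _Layout, config: SimulationConfig, srna: pd.DataFrame) -> None:
    """Fill per-pair sRNA truth flags by scanning the emitted reads.

    Gene-level detection uses the true transcript spans, matching the
    pipeline's intersection against RNA-seq-extended spans (planted reads
    sit well inside or well outside, so the small edge difference between
    true and extended spans never matters); the overlap flag requires full
    containment in the annotated overlap for annotation pairs, or in the
    true overlap for extension-derived pairs (reads there are placed
    centrally, so containment also holds in the slightly narrower overlap
    the pipeline computes from extended spans).
    """
    kept = srna[(srna["length"] >= 21) & (srna["length"] <= 24)]
    starts = kept["start"].to_numpy()
    ends = kept["end"].to_numpy()
    detected = {}
    for gene in layout.genes:
        detected[gene.gene_id] = bool(
            ((starts < gene.true_end) & (ends > gene.true_start)).any()
        )
    by_id = {g.gene_id: g for g in layout.genes}
    for pair in layout.pairs:
        a, b = by_id[pair.gene_a], by_id[pair.gene_b]
        pair.gene_detected_a = detected[pair.gene_a]
        pair.gene_detected_b = detected[pair.gene_b]
        if pair.source == SOURCE_RNASEQ:
            ov_start = max(a.true_start, b.true_start)
            ov_end = min(a.true_end, b.true_end)
        else:
            ov_start = max(a.ann_start, b.ann_start)
            ov_end = min(a.ann_end, b.ann_end)
        pair.overlap_detected = bool(
            ((starts >= ov_start) & (ends <= ov_end)).any()
        )


def simulate(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """Generate one synthetic dataset plus its ground-truth manifest."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    layout = _plant_layout(config, rng)
    _verify_layout(layout, config)
    _design_expression(layout, config, rng)
    _design_cells(layout, config, rng)
    rnaseq = _emit_rnaseq(layout, config, rng)
    _realize_expression(layout, config, rnaseq)
    _realize_cells(layout)
    array = _emit_array(layout, config, rng)
    srna = _emit_srna(layout, config, rng)
    _realize_srna(layout, config, srna)
    truth = GroundTruth(
        genes={g.gene_id: g for g in layout.genes},
        pairs={p.pair_id: p for p in layout.pairs},
        triplet_sets=layout.triplets,
        decoy_gene_ids=layout.decoys,
        total_mapped_reads=len(rnaseq),
    )
    return SimulatedDataset(
        config=config,
        genes=_gene_models(layout, config, annotated=True),
        rnaseq=rnaseq,
        array=array,
        srna=srna,
        truth=truth,
    )


def sample_poisson_counts(
    target_rpms: Sequence[float],
    library_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson read counts with mean target_rpm x library_size / 10^6.

    The count-sampling model behind ``noise_free=False``, exposed directly
    for calibration studies of the RPM>=1 expression gate at realistic
    library depths without materializing alignments.
    """
    means = np.asarray(target_rpms, dtype=float) * library_size / 1e6
    return rng.poisson(means)
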