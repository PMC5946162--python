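"""Coverage tracks, boundary extension, and novel-pair detection."""

import numpy as np
import pytest

from cisnat.coverage import (
    build_coverage,
    detect_novel_pairs,
    extend_all,
    extend_gene_bounds,
)
from cisnat.io import Alignment
from cisnat.pairs import SOURCE_RNASEQ, find_candidate_pairs

from conftest import make_gene


def reads(*spans, chrom="Chr1", strand="+"):
    return [Alignment(chrom, s, e, strand) for s, e in spans]


class TestBuildCoverage:
    def test_depth_counts_covering_reads(self):
        track = build_coverage(reads((100, 150), (100, 150), (100, 150)))
        assert track.depth("Chr1", 120) == 3
        assert track.depth("Chr1", 160) == 0

    def test_empty_alignments_give_zero_track(self):
        track = build_coverage([])
        assert track.depth("Chr1", 5) == 0

    def test_stranded_mode_separates_strands(self):
        alns = [Alignment("Chr1", 100, 150, "+"), Alignment("Chr1", 100, 150, "-")]
        track = build_coverage(alns, "stranded")
        assert track.depth("Chr1", 120, "+") == 1
        assert track.depth("Chr1", 120, "-") == 1
        unstranded = build_coverage(alns, "unstranded")
        assert unstranded.depth("Chr1", 120) == 2


class TestExtension:
    def test_continuous_coverage_extends_to_its_end(self):
        gene = make_gene("A", 100, 500, "+")
        # depth 2 for 120 bp past the gene end, zero afterwards
        track = build_coverage(reads((480, 620), (480, 620)))
        obs = extend_gene_bounds(gene, track)
        assert obs.right_extension == 120
        assert obs.left_extension == 0
        assert (obs.interval.start, obs.interval.end) == (100, 620)

    def test_no_coverage_means_no_extension(self):
        gene = make_gene("A", 100, 500, "+")
        obs = extend_gene_bounds(gene, build_coverage([]))
        assert (obs.left_extension, obs.right_extension) == (0, 0)
        assert obs.interval == gene.interval

    def test_gap_longer_than_max_gap_stops_the_walk(self):
        gene = make_gene("A", 100, 500, "+")
        # depth 2 for 40 bp, 60 bp gap (> 50), then more coverage
        track = build_coverage(
            reads((500, 540), (500, 540), (600, 700), (600, 700))
        )
        obs = extend_gene_bounds(gene, track, min_depth=2, max_gap=50)
        assert obs.right_extension == 40

    def test_gap_within_max_gap_is_bridged(self):
        gene = make_gene("A", 100, 500, "+")
        track = build_coverage(
            reads((500, 540), (500, 540), (580, 700), (580, 700))
        )
        obs = extend_gene_bounds(gene, track, min_depth=2, max_gap=50)
        assert obs.right_extension == 200

    def test_max_extension_cap(self):
        gene = make_gene("A", 100, 500, "+")
        track = build_coverage(reads((450, 5000), (450, 5000)))
        obs = extend_gene_bounds(gene, track, max_extension=300)
        assert obs.right_extension == 300

    def test_left_extension_never_crosses_zero(self):
        gene = make_gene("A", 50, 200, "+")
        track = build_coverage(reads((0, 200), (0, 200)))
        obs = extend_gene_bounds(gene, track, max_extension=2000)
        assert obs.left_extension == 50

    def test_absent_chromosome_gives_zero_extension(self):
        gene = make_gene("A", 100, 500, "+", chrom="Chr9")
        track = build_coverage(reads((480, 600), (480, 600)))
        obs = extend_gene_bounds(gene, track)
        assert (obs.left_extension, obs.right_extension) == (0, 0)

    def test_stranded_coverage_ignores_antisense_reads(self):
        gene = make_gene("A", 100, 500, "+")
        track = build_coverage(reads((480, 620), (480, 620), strand="-"), "stranded")
        obs = extend_gene_bounds(gene, track)
        assert obs.right_extension == 0

    def test_raising_min_depth_never_lengthens_extension(self):
        rng = np.random.default_rng(3)
        gene = make_gene("A", 1000, 1500, "+")
        alns = reads(*[
            (int(s), int(s) + 60)
            for s in rng.integers(1400, 2600, size=80)
        ])
        track = build_coverage(alns)
        prev = None
        for min_depth in (1, 2, 3, 5, 8):
            ext = extend_gene_bounds(gene, track, min_depth=min_depth).right_extension
            if prev is not None:
                assert ext <= prev
            prev = ext

    def test_lowering_max_extension_never_lengthens_extension(self):
        gene = make_gene("A", 100, 500, "+")
        track = build_coverage(reads((450, 3000), (450, 3000)))
        exts = [
            extend_gene_bounds(gene, track, max_extension=cap).right_extension
            for cap in (2000, 1000, 200, 0)
        ]
        assert exts == sorted(exts, reverse=True)

    def test_idempotent_under_rerun(self):
        gene = make_gene("A", 100, 500, "+")
        track = build_coverage(reads((480, 620), (480, 620)))
        first = extend_gene_bounds(gene, track)
        second = extend_gene_bounds(gene, track)
        assert first == second


class TestNovelPairs:
    def make_novel_fixture(self):
        # annotated spans gapped by 10 bp; the true transcripts overlap
        genes = [make_gene("A", 100, 500, "+"), make_gene("B", 510, 900, "-")]
        cov_reads = reads((460, 560), (460, 560))  # joint coverage across the gap
        return genes, cov_reads

    def test_extension_creates_novel_pair(self):
        genes, cov_reads = self.make_novel_fixture()
        track = build_coverage(cov_reads)
        observed = extend_all(genes, track)
        ann = find_candidate_pairs(genes)
        assert ann == []
        (pair,) = detect_novel_pairs(observed, genes, ann)
        assert pair.source == SOURCE_RNASEQ
        # A extends to 560, B to 460: overlap [460, 560)
        assert (pair.overlap.start, pair.overlap.end) == (460, 560)

    def test_subthreshold_extended_overlap_is_not_a_pair(self):
        genes = [make_gene("A", 100, 500, "+"), make_gene("B", 510, 900, "-")]
        # extensions meet but the resulting overlap [498, 518) is only 20 bp
        track = build_coverage(reads((498, 518), (498, 518)))
        observed = extend_all(genes, track)
        assert detect_novel_pairs(observed, genes, []) == []

    def test_annotation_pair_not_reemitted_as_novel(self):
        genes = [make_gene("A", 100, 500, "+"), make_gene("B", 450, 900, "-")]
        track = build_coverage(reads((400, 600), (400, 600)))
        observed = extend_all(genes, track)
        ann = find_candidate_pairs(genes)
        assert len(ann) == 1
        assert detect_novel_pairs(observed, genes, ann) == []

    def test_annotation_pairs_survive_extension(self):
        # extensions only grow spans, so annotated pairs stay detectable
        genes, cov_reads = self.make_novel_fixture()
        genes.append(make_gene("C", 2000, 3000, "+"))
        genes.append(make_gene("D", 2900, 4000, "-"))
        track = build_coverage(cov_reads)
        observed = extend_all(genes, track)
        ann = find_candidate_pairs(genes)
        spans = {o.gene_id: o.interval for o in observed}
        extended = [g.with_interval(spans[g.gene_id]) for g in genes]
        extended_ids = {p.pair_id for p in find_candidate_pairs(extended)}
        assert {p.pair_id for p in ann} <= extended_ids
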