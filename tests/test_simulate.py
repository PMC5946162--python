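"""Synthetic-data generator: planted geometry, determinism, controls."""

import json

import pytest

from cisnat.pairs import brute_force_pairs, find_candidate_pairs
from cisnat.simulate import SimulationConfig, SimulatedDataset, simulate


def test_planted_pair_counts_match_config(default_dataset):
    config = default_dataset.config
    truth = default_dataset.truth
    kinds = [p.kind for p in truth.pairs.values()]
    assert kinds.count("three_prime") == config.n_three_prime
    assert kinds.count("five_prime") == config.n_five_prime
    assert kinds.count("containment") == config.n_containment
    assert kinds.count("novel_three_prime") == config.n_novel
    assert len(truth.triplet_sets) == config.n_triplet_sets
    assert len(truth.pairs) == (
        config.n_three_prime + config.n_five_prime + config.n_containment
        + 2 * config.n_triplet_sets + config.n_novel
    )


def test_annotated_geometry_agrees_with_oracle(default_dataset):
    # the annotation-visible truth pairs are exactly what brute force finds
    want = {
        pid for pid, p in default_dataset.truth.pairs.items()
        if p.source == "annotation"
    }
    got = {p.pair_id for p in brute_force_pairs(default_dataset.genes)}
    assert got == want


def test_decoys_produce_no_pairs(default_dataset):
    decoys = set(default_dataset.truth.decoy_gene_ids)
    assert decoys  # default config plants all three decoy kinds
    for pair in find_candidate_pairs(default_dataset.genes):
        assert pair.gene_a not in decoys
        assert pair.gene_b not in decoys


def test_subthreshold_decoy_sits_exactly_at_21bp(default_dataset):
    # the first sub-threshold unit overlaps by exactly 21 bp: the sharpest
    # negative control for the >21 nt rule
    truth = default_dataset.truth
    decoy_genes = [truth.genes[g] for g in truth.decoy_gene_ids]
    overlaps = []
    for i in range(0, len(decoy_genes) - 1):
        a, b = decoy_genes[i], decoy_genes[i + 1]
        if a.strand != b.strand and a.biotype == b.biotype == "protein_coding":
            ov = min(a.true_end, b.true_end) - max(a.true_start, b.true_start)
            if 0 < ov <= 21:
                overlaps.append(ov)
    assert 21 in overlaps


def test_novel_pairs_are_invisible_in_annotation(default_dataset):
    truth = default_dataset.truth
    ann_ids = {p.pair_id for p in find_candidate_pairs(default_dataset.genes)}
    for pid, pair in truth.pairs.items():
        if pair.source == "rnaseq_extended":
            assert pid not in ann_ids


def test_novel_genes_have_reads_past_annotated_ends(default_dataset):
    truth = default_dataset.truth
    rnaseq = default_dataset.rnaseq
    for pair in truth.pairs.values():
        if pair.source != "rnaseq_extended":
            continue
        for gid in (pair.gene_a, pair.gene_b):
            gene = truth.genes[gid]
            hits = rnaseq[
                (rnaseq.strand == gene.strand)
                & (rnaseq.start < gene.true_end)
                & (rnaseq.end > gene.true_start)
            ]
            assert (hits.end > gene.ann_end).any() or (hits.start < gene.ann_start).any()


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    config = SimulationConfig(seed=42, n_three_prime=4, n_five_prime=2,
                              n_containment=1, n_triplet_sets=1, n_novel=1)
    a_dir, b_dir = tmp_path / "a", tmp_path / "b"
    simulate(config).write(str(a_dir))
    simulate(config).write(str(b_dir))
    for name in ("annotation.gff3", "rnaseq.tsv", "array.tsv", "srna.tsv", "truth.json"):
        assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes()


def test_different_seeds_differ():
    a = simulate(SimulationConfig(seed=1, n_three_prime=3))
    b = simulate(SimulationConfig(seed=2, n_three_prime=3))
    assert not a.rnaseq.equals(b.rnaseq)


def test_truth_manifest_is_serializable(default_dataset, tmp_path):
    paths = default_dataset.write(str(tmp_path))
    with open(paths["truth"]) as fh:
        manifest = json.load(fh)
    assert set(manifest["pairs"]) == set(default_dataset.truth.pairs)
    assert manifest["tallies"] == default_dataset.truth.tallies()


def test_expression_design_is_realized_noise_free(default_dataset):
    # genes designed silent got no reads; expressed genes cleared RPM >= 1
    for gene in default_dataset.truth.genes.values():
        if gene.target_rpm >= 10:
            assert gene.expressed
        else:
            assert not gene.expressed


def test_cell_patterns_consistent_with_array_table(default_dataset):
    table = default_dataset.array.set_index("gene_id")
    for gene in default_dataset.truth.genes.values():
        if not gene.in_array:
            assert gene.gene_id not in table.index
            continue
        row = table.loc[gene.gene_id]
        if gene.cell_pattern == "vc_only":
            assert (row.pollen_call, row.sperm_call) == ("P", "A")
        elif gene.cell_pattern == "silent":
            assert (row.pollen_call, row.sperm_call) == ("A", "A")
        else:  # sperm_only / both_cells: both present, ratio safely <= 3
            assert (row.pollen_call, row.sperm_call) == ("P", "P")
            assert row.pollen_signal / row.sperm_signal <= 3.0


def test_srna_length_decoys_are_planted(default_dataset):
    lengths = set(default_dataset.srna["length"])
    assert 19 in lengths and 30 in lengths


def test_stochastic_mode_differs_from_noise_free():
    noise_free = simulate(SimulationConfig(seed=5, n_three_prime=5))
    noisy = simulate(SimulationConfig(seed=5, n_three_prime=5, noise_free=False))
    assert not noise_free.rnaseq.equals(noisy.rnaseq)


def test_infeasible_counts_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_three_prime=-1)
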