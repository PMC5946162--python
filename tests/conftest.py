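import numpy as np
import pytest

from cisnat.intervals import GeneModel, GenomicInterval, OTHER_BIOTYPE, PROTEIN_CODING
from cisnat.pipeline import PipelineConfig, run_pipeline
from cisnat.simulate import SimulationConfig, simulate


def make_gene(gene_id, start, end, strand, chrom="Chr1", biotype=PROTEIN_CODING):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), biotype)


def random_genome(rng, n_genes, chrom_count=2, chrom_len=50_000):
    """Random gene layout with frequent overlaps of all kinds: the shared
    input generator for scanner-vs-oracle comparisons."""
    genes = []
    for i in range(n_genes):
        chrom = f"Chr{rng.integers(1, chrom_count + 1)}"
        start = int(rng.integers(0, chrom_len))
        length = int(rng.integers(50, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = PROTEIN_CODING if rng.random() < 0.85 else OTHER_BIOTYPE
        genes.append(make_gene(f"R{i:04d}", start, start + length, strand, chrom, biotype))
    return genes


@pytest.fixture(scope="session")
def default_dataset():
    """The default noise-free synthetic dataset (seed 1)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def dataset_dir(default_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    paths = default_dataset.write(str(outdir))
    return paths


@pytest.fixture(scope="session")
def pipeline_result(default_dataset, dataset_dir):
    config = PipelineConfig(
        annotation=dataset_dir["annotation"],
        rnaseq=dataset_dir["rnaseq"],
        array=dataset_dir["array"],
        srna=dataset_dir["srna"],
        strand_mode="stranded",
    )
    return run_pipeline(config)
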