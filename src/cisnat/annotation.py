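"""GFF3 ingestion: gene models normalized to 0-based half-open coordinates.

The reader is built on :mod:`gffutils` (in-memory database). A gene's span is
the union span over the gene feature and all its transcript-level children,
introns included; an optional exon-level mode additionally records exon
spans. Biotype is taken from an annotation attribute when present, otherwise
inferred from the presence of CDS descendants.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import gffutils

from .intervals import (
    GeneModel,
    GenomicInterval,
    OTHER_BIOTYPE,
    PROTEIN_CODING,
    sort_genes,
)

logger = logging.getLogger(__name__)

#: attribute names probed, in order, for a gene's biotype
BIOTYPE_ATTRIBUTES = ("biotype", "gene_biotype", "locus_type", "gene_type")

TRANSCRIPT_TYPES = {
    "mRNA",
    "transcript",
    "ncRNA",
    "lncRNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "miRNA_primary_transcript",
    "pseudogenic_transcript",
}

SPAN_MODES = ("locus", "exon")


class AnnotationError(ValueError):
    """Raised for malformed GFF3 input, carrying the offending line number."""


def _validate_gff3(path: str) -> None:
    # cheap pre-scan so parse failures report a line number
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )


def _biotype_of(db: gffutils.FeatureDB, gene, attribute: Optional[str]) -> str:
    names = (attribute,) + BIOTYPE_ATTRIBUTES if attribute else BIOTYPE_ATTRIBUTES
    for name in names:
        values = gene.attributes.get(name)
        if values:
            return PROTEIN_CODING if values[0] == "protein_coding" else OTHER_BIOTYPE
    # fallback: coding iff the locus has at least one CDS descendant
    for _ in db.children(gene, featuretype="CDS", level=None):
        return PROTEIN_CODING
    return OTHER_BIOTYPE


def read_annotation(
    path: str,
    span_mode: str = "locus",
    biotype_attribute: Optional[str] = None,
) -> list[GeneModel]:
    """Parse gene models from a GFF3 file.

    Parameters
    ----------
    path
        GFF3 file (1-based inclusive coordinates; converted to 0-based
        half-open internally).
    span_mode
        ``"locus"`` (default) records only the union span; ``"exon"``
        additionally records exon spans on each model.
    biotype_attribute
        Attribute name to consult first for the biotype; standard names
        are probed afterwards, then CDS presence decides.

    Returns
    -------
    Gene models sorted by (chrom, start, gene_id). Strandless gene features
    are rejected with a logged warning; malformed lines raise
    :class:`AnnotationError` with the line number.
    """
    if span_mode not in SPAN_MODES:
        raise ValueError(f"span_mode must be one of {SPAN_MODES}, got {span_mode!r}")
    _validate_gff3(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            logger.warning(
                "skipping strandless gene %s at %s:%d-%d",
                gene.id, gene.seqid, gene.start, gene.end,
            )
            continue
        if gene.id in seen:
            raise AnnotationError(f"duplicate gene id {gene.id!r} in {path}")
        seen.add(gene.id)
        # union span over the gene feature and its transcript children,
        # GFF3 1-based inclusive -> 0-based half-open
        start0, end0 = gene.start - 1, gene.end
        for child in db.children(gene, level=1):
            if child.featuretype in TRANSCRIPT_TYPES:
                start0 = min(start0, child.start - 1)
                end0 = max(end0, child.end)
        exons: tuple = ()
        if span_mode == "exon":
            exons = tuple(
                sorted(
                    GenomicInterval(gene.seqid, e.start - 1, e.end, gene.strand)
                    for e in db.children(gene, featuretype="exon", level=None)
                )
            )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                interval=GenomicInterval(gene.seqid, start0, end0, gene.strand),
                biotype=_biotype_of(db, gene, biotype_attribute),
                exon_spans=exons,
            )
        )
    return sort_genes(genes)


def write_annotation(genes: Iterable[GeneModel], path: str, source: str = "cisnat") -> None:
    """Write gene models back to GFF3 (inverse of :func:`read_annotation`)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in sort_genes(list(genes)):
            attrs = f"ID={gene.gene_id};biotype={gene.biotype}"
            out.write(
                "\t".join(
                    (
                        gene.chrom,
                        source,
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )
            for i, exon in enumerate(gene.exon_spans, start=1):
                out.write(
                    "\t".join(
                        (
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}",
                        )
                    )
                    + "\n"
                )
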