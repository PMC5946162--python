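"""Alignment and table I/O.

Read alignments come either from SAM/BAM (via pysam) or from a simple
tab-delimited table with columns ``chrom  start  end  strand`` (0-based
half-open). Small-RNA tables carry two extra columns, ``length`` and
``abundance``. Tables with a header row naming these columns are accepted;
headerless tables are read positionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = ["chrom", "start", "end", "strand"]
SRNA_COLUMNS = ALIGNMENT_COLUMNS + ["length", "abundance"]


@dataclass(frozen=True)
class Alignment:
    """A mapped read span (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str


def _is_sam(path: str) -> bool:
    return path.endswith((".sam", ".bam", ".cram"))


def _read_table(path: str, columns: list[str]) -> pd.DataFrame:
    first = pd.read_csv(path, sep="\t", nrows=0)
    if set(columns).issubset(first.columns):
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=columns)
    return df[columns]


def iter_alignments(path: str) -> Iterator[Alignment]:
    """Yield mapped read spans from SAM/BAM or a tab-delimited table.

    Unmapped or invalid SAM records are skipped; the skip count is logged.
    """
    if _is_sam(path):
        skipped = 0
        mode = "rb" if path.endswith((".bam", ".cram")) else "r"
        with pysam.AlignmentFile(path, mode) as sam:
            for rec in sam.fetch(until_eof=True):
                if rec.is_unmapped or rec.reference_name is None:
                    skipped += 1
                    continue
                yield Alignment(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                )
        if skipped:
            logger.info("skipped %d unmapped/invalid records in %s", skipped, path)
    else:
        df = _read_table(path, ALIGNMENT_COLUMNS)
        for row in df.itertuples(index=False):
            yield Alignment(str(row.chrom), int(row.start), int(row.end), str(row.strand))


def read_alignments(path: str) -> list[Alignment]:
    return list(iter_alignments(path))


def read_srna_table(path: str) -> pd.DataFrame:
    """Small-RNA alignments as a DataFrame with :data:`SRNA_COLUMNS`.

    From SAM/BAM, ``length`` is the aligned span width and ``abundance`` 1.
    """
    if _is_sam(path):
        rows = [
            (a.chrom, a.start, a.end, a.strand, a.end - a.start, 1)
            for a in iter_alignments(path)
        ]
        return pd.DataFrame(rows, columns=SRNA_COLUMNS)
    return _read_table(path, SRNA_COLUMNS)


def write_alignments(alignments, path: str) -> None:
    pd.DataFrame(
        [(a.chrom, a.start, a.end, a.strand) for a in alignments],
        columns=ALIGNMENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
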