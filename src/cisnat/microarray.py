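"""Cell-type assignment from pollen/sperm microarray detection calls.

The ATH1-style detection call per gene is Present (P), Absent (A), or
Marginal (M). Sperm expression is read directly off the sperm call
(P => expressed). Vegetative-cell expression is inferred: the vegetative
cell dominates whole-pollen RNA, so a gene is called VC-expressed when
either (1) both pollen and sperm calls are P and the pollen/sperm signal
ratio exceeds 3 (strict), or (2) the pollen call is P and the sperm call
is A. Marginal calls default to Absent (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import pandas as pd

from .pairs import NatPair

RATIO_THRESHOLD_DEFAULT = 3.0

CALLS = ("P", "A", "M")

STATUS_BOTH = "both"
STATUS_ONE = "one"
STATUS_NEITHER = "neither"
STATUS_UNKNOWN = "unknown"
CELL_STATUSES = (STATUS_BOTH, STATUS_ONE, STATUS_NEITHER, STATUS_UNKNOWN)

ARRAY_COLUMNS = ["gene_id", "pollen_signal", "pollen_call", "sperm_signal", "sperm_call"]


@dataclass(frozen=True)
class ArrayRecord:
    gene_id: str
    pollen_signal: float
    pollen_call: str
    sperm_signal: float
    sperm_call: str

    def __post_init__(self) -> None:
        for call in (self.pollen_call, self.sperm_call):
            if call not in CALLS:
                raise ValueError(f"bad detection call {call!r}")
        if self.pollen_signal < 0 or self.sperm_signal < 0:
            raise ValueError("signals must be non-negative")


@dataclass(frozen=True)
class CellAssignment:
    pair_id: str
    sperm_status: str
    vc_status: str


def _effective(call: str, marginal_as_present: bool) -> str:
    if call == "M":
        return "P" if marginal_as_present else "A"
    return call


def sperm_expressed(record: ArrayRecord, marginal_as_present: bool = False) -> bool:
    """Expressed in sperm iff the sperm call is Present."""
    return _effective(record.sperm_call, marginal_as_present) == "P"


def vc_expressed(
    record: ArrayRecord,
    ratio_threshold: float = RATIO_THRESHOLD_DEFAULT,
    marginal_as_present: bool = False,
) -> bool:
    """Expressed in the vegetative cell per the two-rule test.

    Rule 1: pollen P and sperm P with pollen/sperm signal ratio strictly
    above ``ratio_threshold`` (a zero sperm signal counts as satisfying the
    ratio). Rule 2: pollen P and sperm A.
    """
    pollen = _effective(record.pollen_call, marginal_as_present)
    sperm = _effective(record.sperm_call, marginal_as_present)
    if pollen != "P":
        return False
    if sperm == "A":
        return True
    # both Present: ratio test, sperm_signal == 0 treated as +inf ratio
    if record.sperm_signal == 0:
        return True
    return record.pollen_signal / record.sperm_signal > ratio_threshold


def assign_pair(
    pair: NatPair,
    records: Mapping[str, ArrayRecord],
    ratio_threshold: float = RATIO_THRESHOLD_DEFAULT,
    marginal_as_present: bool = False,
) -> CellAssignment:
    """Sperm and vegetative-cell status of a pair (both/one/neither).

    Either gene missing from the array table makes both statuses unknown.
    """
    rec_a = records.get(pair.gene_a)
    rec_b = records.get(pair.gene_b)
    if rec_a is None or rec_b is None:
        return CellAssignment(pair.pair_id, STATUS_UNKNOWN, STATUS_UNKNOWN)

    def status(flag_a: bool, flag_b: bool) -> str:
        return (STATUS_NEITHER, STATUS_ONE, STATUS_BOTH)[int(flag_a) + int(flag_b)]

    return CellAssignment(
        pair_id=pair.pair_id,
        sperm_status=status(
            sperm_expressed(rec_a, marginal_as_present),
            sperm_expressed(rec_b, marginal_as_present),
        ),
        vc_status=status(
            vc_expressed(rec_a, ratio_threshold, marginal_as_present),
            vc_expressed(rec_b, ratio_threshold, marginal_as_present),
        ),
    )


def read_array_table(path: str) -> Dict[str, ArrayRecord]:
    """Load a gene_id / pollen_signal / pollen_call / sperm_signal /
    sperm_call TSV into a record map."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ARRAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"array table {path} lacks columns {sorted(missing)}")
    records = {}
    for row in df.itertuples(index=False):
        records[str(row.gene_id)] = ArrayRecord(
            gene_id=str(row.gene_id),
            pollen_signal=float(row.pollen_signal),
            pollen_call=str(row.pollen_call),
            sperm_signal=float(row.sperm_signal),
            sperm_call=str(row.sperm_call),
        )
    return records
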