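"""Presence/absence screening of an intron block in an alignment.

The group I intron inserted at the position homologous to SSU position
1506 shows up in an alignment as a contiguous block of columns occupied
in intron-carrying taxa and gapped in taxa that lost it.  Presence is
called positionally — on the fraction of non-gap characters inside the
block — not by motif search.  A helper converts a reference-sequence
coordinate interval (e.g. the insertion point in a reference taxon) to
alignment columns through the reference gap pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CoordinateError
from .nhs_scan import CladePartition
from .seq_data import AlignedSeqSet
from .structure_map import ungapped_to_column

PRESENT = "present"
ABSENT = "absent"


@dataclass
class IntronLocus:
    """1-based inclusive alignment-column interval of the intron block."""

    column_start: int
    column_end: int
    min_occupancy: float = 0.5

    def __post_init__(self) -> None:
        if self.column_start > self.column_end:
            raise CoordinateError(
                f"locus start {self.column_start} > end {self.column_end}"
            )
        if not 0.0 < self.min_occupancy <= 1.0:
            raise CoordinateError("min_occupancy must lie in (0, 1]")


def locus_from_reference(
    aln: AlignedSeqSet,
    ref_taxon: str,
    ref_start: int,
    ref_end: int,
    min_occupancy: float = 0.5,
) -> IntronLocus:
    """Locus from ungapped reference coordinates of ``ref_taxon``."""
    lut = ungapped_to_column(aln, ref_taxon)
    if not (1 <= ref_start <= ref_end <= len(lut)):
        raise CoordinateError(
            f"reference interval {ref_start}-{ref_end} outside 1..{len(lut)}"
        )
    return IntronLocus(lut[ref_start - 1], lut[ref_end - 1], min_occupancy)


def screen_intron(
    aln: AlignedSeqSet, locus: IntronLocus
) -> tuple[dict[str, str], pd.DataFrame]:
    """Call each taxon present/absent for the intron block.

    A taxon is ``present`` iff its non-gap fraction within the block is at
    least ``locus.min_occupancy``.  Returns the call mapping and a report
    DataFrame (taxon, occupancy, state).
    """
    if not (1 <= locus.column_start and locus.column_end <= aln.n_columns):
        raise CoordinateError(
            f"locus {locus.column_start}-{locus.column_end} outside alignment "
            f"1..{aln.n_columns}"
        )
    m = aln.char_matrix()[:, locus.column_start - 1 : locus.column_end]
    occupancy = (m != "-").mean(axis=1)
    states = {
        tid: (PRESENT if occ >= locus.min_occupancy else ABSENT)
        for tid, occ in zip(aln.ids, occupancy)
    }
    report = pd.DataFrame(
        {"taxon": aln.ids, "occupancy": occupancy,
         "state": [states[t] for t in aln.ids]}
    )
    return states, report


def partition_by_intron(
    states: Mapping[str, str], partition: CladePartition
) -> pd.DataFrame:
    """Clade x intron-state contingency with a mixed-clade flag."""
    rows = []
    for clade in partition.clades:
        members = [t for t in partition.members(clade) if t in states]
        n_pres = sum(states[t] == PRESENT for t in members)
        n_abs = len(members) - n_pres
        rows.append(
            {"clade": clade, "n_present": n_pres, "n_absent": n_abs,
             "mixed": n_pres > 0 and n_abs > 0}
        )
    return pd.DataFrame(rows)
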