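"""Non-homoplasious synapomorphy (NHS) scanning and CBC annotation.

An NHS for a target group of clades is a mask-included alignment column
that satisfies the two classical apomorphy criteria:

1. strict conservation inside the target — every target taxon carries the
   same unambiguous base x; and
2. absence of convergence outside — no taxon outside the target carries x.

Gap and ambiguity handling is deliberately conservative: a gap or
ambiguity code *inside* the target breaks strict conservation and rejects
the column; a gap *outside* neither matches nor blocks (it is not state
x); an ambiguity code *outside* whose IUPAC expansion contains x counts as
convergence and rejects the column.

When a secondary-structure :class:`~cladesig.structure_map.PairingMap` is
supplied, NHS columns falling on paired positions are checked for
compensatory base changes: if both partners of a pair are NHS for the same
target, the change from the outside consensus pair to the inside pair is
classified as CBC / HCBC / break.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PartitionError
from .seq_data import ALPHABET, AMBIG_CODES, BASES, IUPAC_EXPAND, AlignedSeqSet
from .structure_map import PairingMap, classify_pair_change


@dataclass
class CladePartition:
    """Assignment of every taxon to exactly one clade label."""

    clade_of: dict[str, str]
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = set(self.clade_of.values())
        if not self.order:
            self.order = sorted(labels)
        else:
            missing = labels - set(self.order)
            if missing:
                raise PartitionError(f"labels missing from order: {sorted(missing)}")

    @property
    def clades(self) -> list[str]:
        present = set(self.clade_of.values())
        return [c for c in self.order if c in present]

    def members(self, label: str) -> list[str]:
        if label not in set(self.clade_of.values()):
            raise PartitionError(f"unknown clade label {label!r}")
        return [t for t, c in self.clade_of.items() if c == label]

    def taxa_of(self, labels: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for lab in labels:
            out.update(self.members(lab))
        return out


@dataclass
class NHSRecord:
    """One diagnostic column for one target clade set."""

    column: int                      # 1-based alignment column
    clade_set: tuple[str, ...]
    state_in: str
    states_out: frozenset[str]
    cbc_partner: int | None = None
    cbc_class: str = "none"
    helix: str | None = None
    nhs_number: int | None = None
    flags: tuple[str, ...] = ()


# precomputed lookup: does a character's IUPAC expansion contain base b?
_CHARS = sorted(ALPHABET)
_CHAR_IDX = {c: k for k, c in enumerate(_CHARS)}
_CONTAINS = np.zeros((len(_CHARS), 4), dtype=bool)
for _c, _k in _CHAR_IDX.items():
    for _b, _bi in zip(BASES, range(4)):
        _CONTAINS[_k, _bi] = _b in IUPAC_EXPAND[_c]


def _encode(m: np.ndarray) -> np.ndarray:
    """Map a character matrix to integer codes over the sorted alphabet."""
    codes = np.zeros(m.shape, dtype=np.int8)
    for c, k in _CHAR_IDX.items():
        codes[m == c] = k
    return codes


def find_nhs(
    aln: AlignedSeqSet,
    partition: CladePartition,
    target: Iterable[str],
    pairing: PairingMap | None = None,
) -> list[NHSRecord]:
    """Scan masked columns for NHS of the union of the target clades.

    Records are sorted by column and numbered in column order.  If
    ``pairing`` is given, CBC annotation is attached (see
    :func:`annotate_cbc`).
    """
    target = tuple(target)
    if not target:
        raise PartitionError("target clade set is empty")
    in_taxa = partition.taxa_of(target)
    in_idx = [i for i, t in enumerate(aln.ids) if t in in_taxa]
    out_idx = [i for i, t in enumerate(aln.ids) if t not in in_taxa]
    if not in_idx:
        raise PartitionError(f"no alignment taxa in target {target}")

    m = aln.char_matrix()
    cols = np.flatnonzero(aln.mask)
    inside = m[np.ix_(in_idx, cols)]
    # criterion 2: every inside taxon carries the same unambiguous base
    first = inside[0]
    conserved = (inside == first).all(axis=0) & np.isin(first, list(BASES))
    records: list[NHSRecord] = []
    if out_idx:
        out_codes = _encode(m[np.ix_(out_idx, cols)])
    base_to_i = {b: i for i, b in enumerate(BASES)}
    for k in np.flatnonzero(conserved):
        x = str(first[k])
        col = int(cols[k]) + 1
        if out_idx:
            # criterion 1: no outside taxon is compatible with x
            if _CONTAINS[out_codes[:, k], base_to_i[x]].any():
                continue
            states_out = frozenset(str(c) for c in np.unique(m[out_idx, cols[k]]))
        else:
            states_out = frozenset()
        records.append(
            NHSRecord(column=col, clade_set=target, state_in=x, states_out=states_out)
        )
    records.sort(key=lambda r: r.column)
    for n, r in enumerate(records, start=1):
        r.nhs_number = n
    if pairing is not None:
        records = annotate_cbc(records, aln, partition, target, pairing)
    return records


def consensus_outside(
    aln: AlignedSeqSet, partition: CladePartition, target: Iterable[str], column: int
) -> tuple[str | None, bool]:
    """Majority unambiguous base among non-target taxa at a 1-based column.

    Returns (base, tie_flag); base is None when no outside taxon carries an
    unambiguous base there.  Ties are broken alphabetically and flagged.
    """
    in_taxa = partition.taxa_of(tuple(target))
    counts: Counter[str] = Counter()
    for tid, seq in zip(aln.ids, aln.seqs):
        if tid in in_taxa:
            continue
        ch = seq[column - 1]
        if ch in BASES:
            counts[ch] += 1
    if not counts:
        return None, False
    top = max(counts.values())
    winners = sorted(b for b, n in counts.items() if n == top)
    return winners[0], len(winners) > 1


def annotate_cbc(
    nhs: list[NHSRecord],
    aln: AlignedSeqSet,
    partition: CladePartition,
    target: Iterable[str],
    pairing: PairingMap,
) -> list[NHSRecord]:
    """Attach CBC/HCBC classification to NHS records on paired columns.

    For an NHS at column i on a paired position with partner column j, the
    pair change (consensus-outside_i, consensus-outside_j) ->
    (inside-state_i, inside-state_j) is classified.  The inside state at j
    is the NHS state when j is itself an NHS for the same target, or the
    uniform unambiguous inside base when j is merely conserved within the
    target (the hemi-CBC case: only one partner of the pair changed).
    When both ends are NHS the class is reported on both records; partners
    on mask-excluded columns are flagged and left unclassified.
    """
    target = tuple(target)
    in_taxa = partition.taxa_of(target)
    in_idx = [i for i, t in enumerate(aln.ids) if t in in_taxa]
    m = aln.char_matrix()
    partner = pairing.partner_of
    by_col = {r.column: r for r in nhs}
    out: list[NHSRecord] = []
    for r in nhs:
        j = partner.get(r.column)
        if j is None:
            out.append(replace(r, cbc_partner=None, cbc_class="none"))
            continue
        pair_key = (min(r.column, j), max(r.column, j))
        helix = pairing.helix.get(pair_key)
        if pair_key in pairing.flagged or not aln.mask[j - 1]:
            out.append(
                replace(
                    r,
                    cbc_partner=j,
                    cbc_class="none",
                    helix=helix,
                    flags=r.flags + ("partner_masked_out",),
                )
            )
            continue
        rj = by_col.get(j)
        if rj is not None:
            inside_j: str | None = rj.state_in
        else:
            col_j = m[in_idx, j - 1]
            uniform = (col_j == col_j[0]).all() and col_j[0] in BASES
            inside_j = str(col_j[0]) if uniform else None
        cons_i, tie_i = consensus_outside(aln, partition, target, r.column)
        cons_j, tie_j = consensus_outside(aln, partition, target, j)
        flags = r.flags
        if tie_i or tie_j:
            flags = flags + ("consensus_tie",)
        if cons_i is None or cons_j is None or inside_j is None:
            cls = "indeterminate"
        else:
            cls = classify_pair_change((cons_i, cons_j), (r.state_in, inside_j))
        out.append(
            replace(r, cbc_partner=j, cbc_class=cls, helix=helix, flags=flags)
        )
    return out


def nhs_census(
    aln: AlignedSeqSet,
    partition: CladePartition,
    pairing: PairingMap | None = None,
    clade_sets: Sequence[Iterable[str]] | None = None,
    whole_group_label: str = "ALL",
) -> tuple[pd.DataFrame, dict[str, list[NHSRecord]]]:
    """NHS counts per target clade set, plus the whole-group row.

    ``clade_sets`` defaults to one singleton set per clade.  A final row
    targets the union of every clade mentioned in ``clade_sets`` at once
    (the genus-level scan; when the union covers all taxa there is no
    outside set, the convergence criterion is vacuous, and the row counts
    strictly conserved columns).

    Returns the census DataFrame and a dict target-label -> records.
    """
    if clade_sets is None:
        clade_sets = [(c,) for c in partition.clades]
    targets = [tuple(cs) for cs in clade_sets]
    union = tuple(c for c in partition.order
                  if any(c in t for t in targets))
    all_clades = union
    if all_clades not in targets:
        targets.append(all_clades)
    rows = []
    record_map: dict[str, list[NHSRecord]] = {}
    for tgt in targets:
        label = whole_group_label if tgt == all_clades else "+".join(tgt)
        recs = find_nhs(aln, partition, tgt, pairing)
        record_map[label] = recs
        rows.append(
            {
                "target": label,
                "n_nhs": len(recs),
                "n_cbc": sum(r.cbc_class == "CBC" for r in recs),
                "n_hcbc": sum(r.cbc_class == "HCBC" for r in recs),
                "columns": ",".join(str(r.column) for r in recs),
            }
        )
    return pd.DataFrame(rows), record_map


def nhs_table_report(records: Sequence[NHSRecord], path: str | Path) -> None:
    """Write NHS records as a TSV (one row per record, sorted by column)."""
    cols = [
        "nhs_number", "column", "helix", "clade_set", "state_in",
        "states_out", "cbc_partner", "cbc_class", "flags",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in sorted(records, key=lambda r: r.column):
            fh.write(
                "\t".join(
                    [
                        str(r.nhs_number if r.nhs_number is not None else ""),
                        str(r.column),
                        r.helix or "",
                        "+".join(r.clade_set),
                        r.state_in,
                        ",".join(sorted(r.states_out)),
                        str(r.cbc_partner if r.cbc_partner is not None else ""),
                        r.cbc_class,
                        ",".join(r.flags),
                    ]
                )
                + "\n"
            )


def read_nhs_table(path: str | Path) -> list[NHSRecord]:
    """Read a TSV written by :func:`nhs_table_report`."""
    records: list[NHSRecord] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                NHSRecord(
                    nhs_number=int(f[0]) if f[0] else None,
                    column=int(f[1]),
                    helix=f[2] or None,
                    clade_set=tuple(f[3].split("+")) if f[3] else (),
                    state_in=f[4],
                    states_out=frozenset(f[5].split(",")) if f[5] else frozenset(),
                    cbc_partner=int(f[6]) if f[6] else None,
                    cbc_class=f[7],
                    flags=tuple(f[8].split(",")) if f[8] else (),
                )
            )
    return records
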