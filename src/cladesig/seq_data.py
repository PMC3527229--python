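"""Aligned-sequence container, column masking, clone deduplication.

The central object is :class:`AlignedSeqSet`: an aligned set of IUPAC DNA
sequences with unique taxon ids, optional per-taxon metadata (sampling-site
code, clade label) and a boolean column mask.  The mask models the
"unambiguously aligned positions" convention of rDNA phylogenetics: all
downstream statistics (distances, rate tests, diagnostic-column scans) are
computed on mask-included columns only.

Masks can be built algorithmically from per-column gap/ambiguity fractions
(:func:`build_mask`) or supplied explicitly as a list of 1-based columns
(:func:`mask_from_columns`) to reproduce a manually curated alignment
region.  All reported coordinates in this package are 1-based alignment
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    IdCollisionError,
    MetadataError,
)

#: unambiguous nucleotide states
BASES = "ACGT"

#: IUPAC ambiguity codes (gap excluded)
AMBIG_CODES = "RYSWKMBDHVN"

#: full alphabet accepted after normalisation
ALPHABET = frozenset(BASES + AMBIG_CODES + "-")

#: expansion of every alphabet character into the unambiguous bases it covers
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
    "-": frozenset(),
}


def normalize_seq(seq: str) -> str:
    """Normalise one sequence: uppercase, U->T, '.'->'-'.

    Raises
    ------
    AlphabetError
        if a character outside the IUPAC DNA alphabet remains.
    """
    s = seq.upper().replace("U", "T").replace(".", "-")
    bad = set(s) - ALPHABET
    if bad:
        raise AlphabetError(f"illegal characters {sorted(bad)} in sequence")
    return s


@dataclass
class AlignedSeqSet:
    """An aligned set of DNA sequences with a column mask.

    Parameters
    ----------
    ids
        Unique taxon labels, in alignment order.
    seqs
        Normalised sequences, one per taxon, all the same length.
    mask
        Boolean vector over columns; True = included.  Defaults to all-True.
    site_codes
        Optional taxon -> sampling-site label.
    clade_of
        Optional taxon -> clade label.
    """

    ids: list[str]
    seqs: list[str]
    mask: np.ndarray = None  # type: ignore[assignment]
    site_codes: dict[str, str] | None = None
    clade_of: dict[str, str] | None = None
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentShapeError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise IdCollisionError(f"duplicate taxon ids: {sorted(dupes)}")
        if not self.seqs:
            raise AlignmentShapeError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        self.seqs = [normalize_seq(s) for s in self.seqs]
        if self.mask is None:
            self.mask = np.ones(self.n_columns, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_columns,):
                raise AlignmentShapeError(
                    f"mask length {self.mask.size} != alignment length "
                    f"{self.n_columns}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    def index_of(self, taxon: str) -> int:
        try:
            return self.ids.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def seq_of(self, taxon: str) -> str:
        return self.seqs[self.index_of(taxon)]

    def char_matrix(self) -> np.ndarray:
        """(n_taxa, n_columns) matrix of single characters (cached)."""
        if self._matrix is None or self._matrix.shape != (self.n_taxa, self.n_columns):
            self._matrix = np.array([list(s) for s in self.seqs], dtype="<U1")
        return self._matrix

    def with_mask(self, mask: np.ndarray) -> "AlignedSeqSet":
        """A copy of this set with a different column mask."""
        return replace(self, mask=np.asarray(mask, dtype=bool), _matrix=None)


def read_alignment(
    path: str | Path,
    site_codes: Mapping[str, str] | None = None,
    clade_of: Mapping[str, str] | None = None,
) -> AlignedSeqSet:
    """Read an aligned FASTA file.

    Ids are the header token up to the first whitespace.  Sequences are
    normalised (uppercase, U->T, '.'->'-').  All records must be the same
    length and ids must be unique.
    """
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IdCollisionError(f"duplicate taxon id {rec.id!r} in {path}")
        seen.add(rec.id)
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise AlignmentShapeError(f"no records in {path}")
    return AlignedSeqSet(
        ids=ids,
        seqs=seqs,
        site_codes=dict(site_codes) if site_codes is not None else None,
        clade_of=dict(clade_of) if clade_of is not None else None,
    )


def write_alignment(aln: AlignedSeqSet, path: str | Path, width: int = 70) -> None:
    """Write the alignment as FASTA (wrap at `width` characters)."""
    with open(path, "w") as fh:
        for tid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_mask(
    aln: AlignedSeqSet,
    max_gap_frac: float = 0.05,
    max_ambig_frac: float = 0.05,
) -> np.ndarray:
    """Boolean column mask excluding gap-rich / ambiguity-rich columns.

    A column is included iff its gap fraction is <= ``max_gap_frac`` and its
    ambiguity-code fraction is <= ``max_ambig_frac``.  Does not mutate the
    input; assign the result via :meth:`AlignedSeqSet.with_mask`.
    """
    if not (0.0 <= max_gap_frac <= 1.0 and 0.0 <= max_ambig_frac <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    m = aln.char_matrix()
    gap_frac = (m == "-").mean(axis=0)
    ambig = np.isin(m, list(AMBIG_CODES))
    ambig_frac = ambig.mean(axis=0)
    return (gap_frac <= max_gap_frac) & (ambig_frac <= max_ambig_frac)


def mask_from_columns(columns: Iterable[int], n_columns: int) -> np.ndarray:
    """Mask from an explicit list of 1-based included columns."""
    mask = np.zeros(n_columns, dtype=bool)
    for c in columns:
        if not 1 <= c <= n_columns:
            raise ValueError(f"column {c} outside 1..{n_columns}")
        mask[c - 1] = True
    return mask


def mask_to_columns(mask: np.ndarray) -> list[int]:
    """1-based included columns of a mask."""
    return [int(i) + 1 for i in np.flatnonzero(np.asarray(mask, dtype=bool))]


def read_mask_tsv(path: str | Path, n_columns: int) -> np.ndarray:
    """Read a mask stored as one 1-based included column per line."""
    cols = [int(line.split()[0]) for line in open(path) if line.strip()]
    return mask_from_columns(cols, n_columns)


def write_mask_tsv(mask: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in mask_to_columns(mask):
            fh.write(f"{c}\n")


# ---------------------------------------------------------------------------
# clone deduplication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneRecord:
    """One sequence type: a set of taxa with identical gap-stripped sequences."""

    type_id: str
    representative: str
    members: tuple[str, ...]
    sites: frozenset[str] | None = None

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class CloneTable:
    """Partition of taxa into sequence types (clones)."""

    records: list[CloneRecord]

    @property
    def n_types(self) -> int:
        return len(self.records)

    @property
    def type_of(self) -> dict[str, str]:
        return {m: r.type_id for r in self.records for m in r.members}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type_id": [r.type_id for r in self.records],
                "representative": [r.representative for r in self.records],
                "n_members": [r.count for r in self.records],
                "members": [",".join(r.members) for r in self.records],
                "sites": [
                    ",".join(sorted(r.sites)) if r.sites is not None else ""
                    for r in self.records
                ],
            }
        )


def dedup_clones(aln: AlignedSeqSet, use_masked_columns: bool = False) -> CloneTable:
    """Group taxa whose sequences are identical after gap stripping.

    Two taxa share a type iff their full gap-stripped normalised sequences
    are identical (clones are compared before masking).  Set
    ``use_masked_columns=True`` to compare only mask-included columns
    (gaps still stripped) instead.  The representative of a type is the
    lexicographically smallest member id.
    """
    keys: dict[str, list[str]] = {}
    cols = np.flatnonzero(aln.mask) if use_masked_columns else None
    for tid, seq in zip(aln.ids, aln.seqs):
        if cols is not None:
            seq = "".join(seq[i] for i in cols)
        key = seq.replace("-", "")
        keys.setdefault(key, []).append(tid)
    records = []
    groups = sorted(keys.values(), key=lambda ms: min(ms))
    for k, members in enumerate(groups, start=1):
        members = tuple(sorted(members))
        sites = None
        if aln.site_codes is not None:
            sites = frozenset(
                aln.site_codes[m] for m in members if m in aln.site_codes
            )
        records.append(
            CloneRecord(
                type_id=f"T{k:03d}",
                representative=members[0],
                members=members,
                sites=sites,
            )
        )
    return CloneTable(records=records)


def clone_site_summary(
    ct: CloneTable, site_codes: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Incidence of sequence types across sampling sites.

    Returns
    -------
    per_type, per_site : DataFrame
        ``per_type`` has one row per sequence type with its occurrence
        count (number of accessions) and number of distinct sites;
        ``per_site`` has one row per site with its number of accessions
        and number of distinct types.
    """
    for r in ct.records:
        for m in r.members:
            if m not in site_codes:
                raise MetadataError(f"taxon {m!r} has no site code")
    per_type = pd.DataFrame(
        {
            "type_id": [r.type_id for r in ct.records],
            "n_accessions": [r.count for r in ct.records],
            "n_sites": [len({site_codes[m] for m in r.members}) for r in ct.records],
        }
    )
    type_of = ct.type_of
    rows: dict[str, dict[str, set | int]] = {}
    for taxon, site in site_codes.items():
        if taxon not in type_of:
            continue
        d = rows.setdefault(site, {"n_accessions": 0, "types": set()})
        d["n_accessions"] += 1  # type: ignore[operator]
        d["types"].add(type_of[taxon])  # type: ignore[union-attr]
    per_site = pd.DataFrame(
        {
            "site": list(rows),
            "n_accessions": [d["n_accessions"] for d in rows.values()],
            "n_types": [len(d["types"]) for d in rows.values()],  # type: ignore[arg-type]
        }
    ).sort_values("site", ignore_index=True)
    return per_type, per_site


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (taxon, label) into a dict."""
    out: dict[str, str] = {}
    for line in open(path):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise MetadataError(f"bad map line: {line!r}")
        if parts[0] in out:
            raise IdCollisionError(f"duplicate taxon {parts[0]!r} in {path}")
        out[parts[0]] = parts[1]
    return out


def write_taxon_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")
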