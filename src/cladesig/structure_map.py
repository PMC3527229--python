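"""rRNA secondary-structure pairing maps on alignment columns.

A folded reference sequence (CT file or Vienna dot-bracket) defines which
positions pair in the rRNA helix model.  :func:`lift_to_alignment` moves
those reference-coordinate pairs onto 1-based alignment columns through the
gap pattern of the reference taxon, producing a :class:`PairingMap` that the
diagnostic-column scanner uses to call compensatory base changes.

Pair-change classification follows the standard rRNA covariation
convention: canonical pairing is Watson-Crick plus the G-T (G-U) wobble; a
compensatory base change (CBC) changes both partners while retaining
pairing, a hemi-CBC (HCBC) changes exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import MappingError, StructureError, StructureParseError
from .seq_data import AlignedSeqSet, BASES

#: canonical base pairs, wobble included
CANONICAL_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

#: classification outcomes of classify_pair_change
PAIR_CHANGE_CLASSES = ("CBC", "HCBC", "break", "none", "indeterminate")


@dataclass
class PairingMap:
    """Partner relation over 1-based alignment columns.

    Attributes
    ----------
    pairs
        Set of unordered column pairs (i, j) with i < j.
    helix
        Optional pair -> helix label (pass-through strings, e.g. "29",
        "E23_1"; helix nomenclature is never recomputed here).
    flagged
        Pairs with at least one end on a mask-excluded column; they are
        retained in ``pairs`` but marked so CBC calls can report them.
    """

    pairs: set[tuple[int, int]]
    helix: dict[tuple[int, int], str] = field(default_factory=dict)
    flagged: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise StructureError(f"column {i} paired with itself")
            for c in (i, j):
                if c in seen:
                    raise StructureError(f"column {c} appears in two pairs")
                seen.add(c)

    @property
    def partner_of(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def helix_of(self, column: int) -> str | None:
        for (i, j), label in self.helix.items():
            if column in (i, j):
                return label
        return None


def _canonical(pairs: Iterable[tuple[int, int]]) -> set[tuple[int, int]]:
    return {(min(i, j), max(i, j)) for i, j in pairs}


def parse_ct(path: str | Path) -> set[tuple[int, int]]:
    """Parse a CT file (Zuker/mfold dialect) into reference-coordinate pairs.

    Expected format: a header line starting with the position count, then
    one row per position: index, base, previous, next, partner, natural
    index.  Unpaired positions have partner 0; each pair is returned once
    as (i, j) with i < j.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError(f"empty CT file {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"bad CT header: {lines[0]!r}") from None
    rows = lines[1:]
    if len(rows) != n:
        raise StructureParseError(f"CT header says {n} rows, found {len(rows)}")
    partner = [0] * (n + 1)
    for row in rows:
        parts = row.split()
        if len(parts) < 6:
            raise StructureParseError(f"short CT row: {row!r}")
        try:
            idx, p = int(parts[0]), int(parts[4])
        except ValueError:
            raise StructureParseError(f"non-numeric CT row: {row!r}") from None
        if not 1 <= idx <= n:
            raise StructureParseError(f"CT index {idx} outside 1..{n}")
        if p < 0 or p > n:
            raise StructureParseError(f"CT partner {p} outside 0..{n}")
        partner[idx] = p
    for i in range(1, n + 1):
        p = partner[i]
        if p and partner[p] != i:
            raise StructureError(
                f"asymmetric CT pairing: partner[{i}]={p} but partner[{p}]={partner[p]}"
            )
    return _canonical((i, partner[i]) for i in range(1, n + 1) if partner[i] > i)


def parse_dotbracket(seq: str, struct: str) -> set[tuple[int, int]]:
    """Parse a Vienna dot-bracket string into 1-based pairs.

    Only '.', '(' and ')' are supported; brackets must balance.
    """
    if len(seq) != len(struct):
        raise StructureParseError(
            f"sequence length {len(seq)} != structure length {len(struct)}"
        )
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(struct, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureParseError(f"unsupported structure character {ch!r}")
    if stack:
        raise StructureError(f"unbalanced '(' at positions {stack}")
    return pairs


def ungapped_to_column(aln: AlignedSeqSet, ref_taxon: str) -> list[int]:
    """1-based alignment column of each ungapped position of ``ref_taxon``.

    Element k-1 is the column holding the k-th non-gap character.
    """
    seq = aln.seq_of(ref_taxon)
    return [col for col, ch in enumerate(seq, start=1) if ch != "-"]


def lift_to_alignment(
    pairs: Iterable[tuple[int, int]],
    aln: AlignedSeqSet,
    ref_taxon: str,
    helix: Mapping[tuple[int, int], str] | None = None,
) -> PairingMap:
    """Lift reference-coordinate pairs onto alignment columns.

    Reference position k maps to the alignment column holding the k-th
    non-gap character of ``ref_taxon``.  Pairs with an end on a
    mask-excluded column are retained but flagged.  Helix labels (keyed by
    reference-coordinate pair) are carried across.
    """
    lut = ungapped_to_column(aln, ref_taxon)
    lifted: set[tuple[int, int]] = set()
    lifted_helix: dict[tuple[int, int], str] = {}
    flagged: set[tuple[int, int]] = set()
    helix = dict(helix) if helix else {}
    for i, j in pairs:
        for c in (i, j):
            if not 1 <= c <= len(lut):
                raise MappingError(
                    f"reference position {c} beyond ungapped length {len(lut)} "
                    f"of {ref_taxon!r}"
                )
        a, b = sorted((lut[i - 1], lut[j - 1]))
        lifted.add((a, b))
        key = (min(i, j), max(i, j))
        if key in helix:
            lifted_helix[(a, b)] = helix[key]
        if not (aln.mask[a - 1] and aln.mask[b - 1]):
            flagged.add((a, b))
    return PairingMap(pairs=lifted, helix=lifted_helix, flagged=flagged)


def classify_pair_change(
    pair_before: tuple[str, str], pair_after: tuple[str, str]
) -> str:
    """Classify a change of one structural base pair.

    Returns one of ``"CBC"`` (both partners changed, pairing retained
    before and after), ``"HCBC"`` (exactly one partner changed, pairing
    retained), ``"break"`` (the after-state does not pair), ``"none"``
    (no change, or pairing gained where the before-state did not pair) or
    ``"indeterminate"`` (gap/ambiguity code in either state).
    """
    before = tuple(b.upper() for b in pair_before)
    after = tuple(a.upper() for a in pair_after)
    if any(ch not in BASES for ch in before + after):
        return "indeterminate"
    if before == after:
        return "none"
    if after not in CANONICAL_PAIRS:
        return "break"
    if before not in CANONICAL_PAIRS:
        return "none"
    n_changed = (before[0] != after[0]) + (before[1] != after[1])
    return "CBC" if n_changed == 2 else "HCBC"


def read_helix_labels(path: str | Path) -> dict[tuple[int, int], str]:
    """Read a helix-label TSV: column_start, column_end, label."""
    out: dict[tuple[int, int], str] = {}
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        a, b, label = line.rstrip("\n").split("\t")[:3]
        i, j = sorted((int(a), int(b)))
        out[(i, j)] = label
    return out
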