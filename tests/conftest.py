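"""Shared fixtures and independent oracle helpers.

The oracles here are deliberately naive (pure-python double loops over
taxa and columns) and independent of the vectorised implementations they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cladesig.seq_data import AlignedSeqSet

BASES = "ACGT"
AMBIG = "RYSWKMBDHVN"
EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "-": "",
}


def random_alignment(
    rng: np.random.Generator,
    n_taxa: int,
    n_cols: int,
    gap_frac: float = 0.05,
    ambig_frac: float = 0.02,
    n_clades: int | None = None,
) -> AlignedSeqSet:
    """Random alignment over the full IUPAC alphabet with clade labels."""
    chars = list(BASES) + ["-"] + list(AMBIG)
    p_base = (1.0 - gap_frac - ambig_frac) / 4.0
    probs = [p_base] * 4 + [gap_frac] + [ambig_frac / len(AMBIG)] * len(AMBIG)
    m = rng.choice(chars, size=(n_taxa, n_cols), p=probs)
    ids = [f"t{k:02d}" for k in range(n_taxa)]
    clade_of = None
    if n_clades:
        labels = [chr(ord("A") + rng.integers(0, n_clades)) for _ in ids]
        # ensure every clade is represented
        for c in range(n_clades):
            labels[c % n_taxa] = chr(ord("A") + c)
        clade_of = dict(zip(ids, labels))
    return AlignedSeqSet(
        ids=ids, seqs=["".join(r) for r in m], clade_of=clade_of
    )


def brute_force_nhs(aln: AlignedSeqSet, target_taxa: set[str]) -> dict[int, str]:
    """Naive NHS scan: 1-based column -> diagnostic state.

    A masked column is diagnostic iff all target taxa share the same
    unambiguous base x (gap/ambiguity inside rejects) and no outside
    taxon's character expansion contains x.
    """
    out: dict[int, str] = {}
    inside = [s for t, s in zip(aln.ids, aln.seqs) if t in target_taxa]
    outside = [s for t, s in zip(aln.ids, aln.seqs) if t not in target_taxa]
    for c in range(aln.n_columns):
        if not aln.mask[c]:
            continue
        states = {s[c] for s in inside}
        if len(states) != 1:
            continue
        x = states.pop()
        if x not in BASES:
            continue
        if any(x in EXPAND[s[c]] for s in outside):
            continue
        out[c + 1] = x
    return out


def brute_force_diff(a: str, b: str, mask) -> int:
    """Naive masked pairwise difference count."""
    n = 0
    for c, (ca, cb) in enumerate(zip(a, b)):
        if mask[c] and ca in BASES and cb in BASES and ca != cb:
            n += 1
    return n


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def toy_alignment():
    """5 taxa, clades A (t1,t2) and B (t3,t4,t5)."""
    return AlignedSeqSet(
        ids=["t1", "t2", "t3", "t4", "t5"],
        seqs=[
            "AACGTACGT",
            "AACGTACGA",
            "CACGTTCGT",
            "CACGTTCGT",
            "CACGATCGT",
        ],
        clade_of={"t1": "A", "t2": "A", "t3": "B", "t4": "B", "t5": "B"},
    )
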