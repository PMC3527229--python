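"""Tajima-style relative-rate tests between taxa and between groups.

For two ingroup sequences a, b and an outgroup sequence, Tajima's (1993)
1D test counts, over mask-included columns where all three carry
unambiguous bases, the sites supporting an extra change on each lineage:

    n_a = #{a != b and b == outgroup}   (change on lineage a)
    n_b = #{a != b and a == outgroup}   (change on lineage b)

Under rate equality n_a and n_b are exchangeable and
chi2 = (n_a - n_b)^2 / (n_a + n_b) is asymptotically chi-square with one
degree of freedom.  Significance stars follow the classical reporting
convention: N.S. for p > 0.05, then * (0.01 < p <= 0.05),
** (0.005 < p <= 0.01), *** (p <= 0.005).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentShapeError, PartitionError
from .seq_data import BASES, AlignedSeqSet

STAR_LEVELS = ("N.S.", "*", "**", "***")


def stars_from_p(p: float) -> str:
    """Significance class: p>0.05 N.S.; (0.01,0.05] *; (0.005,0.01] **; <=0.005 ***."""
    if p > 0.05:
        return "N.S."
    if p > 0.01:
        return "*"
    if p > 0.005:
        return "**"
    return "***"


@dataclass
class RateTestResult:
    taxon_a: str
    taxon_b: str
    outgroup: str
    n_a: int
    n_b: int
    chi2: float
    p: float
    stars: str


def tajima_test(
    a: str, b: str, og: str, mask: np.ndarray,
    labels: tuple[str, str, str] = ("a", "b", "outgroup"),
) -> RateTestResult:
    """Tajima's relative-rate test for two sequences against an outgroup.

    Only masked columns where all three sequences carry unambiguous bases
    are used.  When no informative site exists (n_a + n_b = 0) the test is
    degenerate: chi2 = 0, p = 1.
    """
    if not (len(a) == len(b) == len(og)):
        raise AlignmentShapeError(
            f"length mismatch: {len(a)}, {len(b)}, {len(og)}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(a):
        raise AlignmentShapeError("mask length does not match sequences")
    aa = np.array(list(a), dtype="<U1")
    bb = np.array(list(b), dtype="<U1")
    oo = np.array(list(og), dtype="<U1")
    bases = list(BASES)
    ok = (
        mask
        & np.isin(aa, bases)
        & np.isin(bb, bases)
        & np.isin(oo, bases)
    )
    differ = ok & (aa != bb)
    n_a = int((differ & (bb == oo)).sum())
    n_b = int((differ & (aa == oo)).sum())
    if n_a + n_b == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (n_a - n_b) ** 2 / (n_a + n_b)
        p = float(stats.chi2.sf(chi2, df=1))
    return RateTestResult(
        taxon_a=labels[0], taxon_b=labels[1], outgroup=labels[2],
        n_a=n_a, n_b=n_b, chi2=float(chi2), p=p, stars=stars_from_p(p),
    )


def group_rate_tests(
    aln: AlignedSeqSet,
    groups: Mapping[str, Iterable[str]],
    outgroup: Iterable[str],
    group_order: Sequence[str] | None = None,
    group_pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative-rate tests for every cross-group taxon pair and outgroup taxon.

    Parameters
    ----------
    groups
        group label -> member taxa.  Groups must be disjoint and must not
        contain outgroup taxa.
    outgroup
        Outgroup taxon ids (each is used in turn as the reference).

    Returns
    -------
    stars, detail : DataFrame
        ``stars`` is a square group matrix (lower triangle filled) whose
        cell is the star class of the median-chi-square pair for that
        group combination; ``detail`` retains every individual test.
    """
    groups = {g: list(members) for g, members in groups.items()}
    outgroup = list(outgroup)
    for g, members in groups.items():
        if not members:
            raise PartitionError(f"group {g!r} is empty")
        for t in members:
            if t not in aln.ids:
                raise PartitionError(f"group {g!r} member {t!r} not in alignment")
    og_set = set(outgroup)
    for g, members in groups.items():
        overlap = og_set & set(members)
        if overlap:
            raise PartitionError(f"outgroup taxa {sorted(overlap)} inside group {g!r}")
    all_members = [t for ms in groups.values() for t in ms]
    if len(all_members) != len(set(all_members)):
        raise PartitionError("groups are not disjoint")
    for t in outgroup:
        if t not in aln.ids:
            raise PartitionError(f"outgroup taxon {t!r} not in alignment")

    order = list(group_order) if group_order else sorted(groups)
    if group_pairs is None:
        pairs = list(combinations(order, 2))
    else:
        pairs = [tuple(p) for p in group_pairs]
        for ga, gb in pairs:
            if ga == gb:
                raise PartitionError(f"group {ga!r} tested against itself")
            for g in (ga, gb):
                if g not in groups:
                    raise PartitionError(f"unknown group {g!r}")
    detail_rows = []
    stars = pd.DataFrame("", index=order, columns=order)
    for ga, gb in pairs:
        results: list[RateTestResult] = []
        for ta, tb, og in product(groups[ga], groups[gb], outgroup):
            r = tajima_test(
                aln.seq_of(ta), aln.seq_of(tb), aln.seq_of(og), aln.mask,
                labels=(ta, tb, og),
            )
            results.append(r)
            detail_rows.append(
                {"group_a": ga, "group_b": gb, "taxon_a": ta, "taxon_b": tb,
                 "outgroup": og, "n_a": r.n_a, "n_b": r.n_b,
                 "chi2": r.chi2, "p": r.p, "stars": r.stars}
            )
        # group cell: star class of the median-chi2 pair (lower median)
        results.sort(key=lambda r: r.chi2)
        med = results[(len(results) - 1) // 2]
        stars.loc[gb, ga] = med.stars
    detail = pd.DataFrame(detail_rows)
    return stars, detail
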