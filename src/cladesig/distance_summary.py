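"""Pairwise differences and percent p-distances on masked columns.

Distances follow the fixed-denominator convention of classic rDNA clade
comparisons: the percent distance between two taxa is 100 times the number
of masked columns at which both carry unambiguous, differing bases,
divided by the *total* number of masked columns (not by the number of
pairwise-comparable columns).  Columns with a gap or ambiguity code in
either taxon contribute zero differences.  A pairwise-comparable
denominator is available behind a flag for sensitivity analysis.

Clade summaries pair the minimum percent distance with the maximum
nucleotide difference across clades (the half-matrix convention: distances
upper right, differences lower left), and report within-clade ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentShapeError, PartitionError
from .nhs_scan import CladePartition
from .seq_data import BASES, AlignedSeqSet


@dataclass
class DistanceMatrix:
    """Nucleotide-difference counts and percent distances for all taxon pairs."""

    taxa: list[str]
    diff: np.ndarray          # integer nt differences
    dist: np.ndarray          # percent distances
    denominator: int          # masked column count (fixed-denominator mode)
    pairwise_denominator: bool = False

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame(self.diff, index=self.taxa, columns=self.taxa),
            pd.DataFrame(self.dist, index=self.taxa, columns=self.taxa),
        )


def pairwise_differences(a: str, b: str, mask: np.ndarray) -> int:
    """Count masked columns where both sequences carry differing unambiguous bases."""
    if len(a) != len(b):
        raise AlignmentShapeError(f"length mismatch: {len(a)} vs {len(b)}")
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(a):
        raise AlignmentShapeError("mask length does not match sequences")
    aa = np.array(list(a), dtype="<U1")
    bb = np.array(list(b), dtype="<U1")
    ok = np.isin(aa, list(BASES)) & np.isin(bb, list(BASES)) & mask
    return int((ok & (aa != bb)).sum())


def distance_matrix(
    aln: AlignedSeqSet, pairwise_denominator: bool = False
) -> DistanceMatrix:
    """All-pairs difference counts and percent distances on masked columns.

    With ``pairwise_denominator=True`` each percent value divides by that
    pair's number of comparable columns instead of the fixed masked total.
    """
    if aln.n_taxa < 2:
        raise AlignmentShapeError("need at least 2 taxa for a distance matrix")
    m = aln.char_matrix()
    cols = np.flatnonzero(aln.mask)
    sub = m[:, cols]
    unamb = np.isin(sub, list(BASES))
    n = aln.n_taxa
    diff = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = unamb[i] & unamb[i + 1 :]
        d = both & (sub[i] != sub[i + 1 :])
        diff[i, i + 1 :] = d.sum(axis=1)
        comp[i, i + 1 :] = both.sum(axis=1)
    diff = diff + diff.T
    comp = comp + comp.T
    denominator = int(aln.mask.sum())
    if pairwise_denominator:
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.where(comp > 0, 100.0 * diff / np.maximum(comp, 1), 0.0)
    else:
        dist = 100.0 * diff / denominator
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(
        taxa=list(aln.ids),
        diff=diff,
        dist=dist,
        denominator=denominator,
        pairwise_denominator=pairwise_denominator,
    )


def percent_distance_exact(diff: int, denominator: int) -> Fraction:
    """Exact rational percent distance 100*diff/denominator."""
    return Fraction(100 * diff, denominator)


@dataclass
class CladeDistanceSummary:
    """Half-matrix style clade summary.

    ``min_dist``/``max_diff`` are square DataFrames over clades holding the
    minimum percent distance and the maximum nucleotide difference over
    cross-clade taxon pairs; ``mean_dist``/``mean_diff`` hold the means;
    ``within`` holds per-clade min-max ranges of distance and difference
    over internal pairs (0-0 for singleton clades).
    """

    clades: list[str]
    min_dist: pd.DataFrame
    max_diff: pd.DataFrame
    mean_dist: pd.DataFrame
    mean_diff: pd.DataFrame
    within: pd.DataFrame


def clade_summary(dm: DistanceMatrix, partition: CladePartition) -> CladeDistanceSummary:
    """Summarise a distance matrix over a clade partition."""
    unknown = [t for t in dm.taxa if t not in partition.clade_of]
    if unknown:
        raise PartitionError(f"taxa without clade label: {unknown}")
    clades = partition.clades
    idx = {c: [k for k, t in enumerate(dm.taxa) if partition.clade_of[t] == c]
           for c in clades}
    nc = len(clades)
    min_dist = np.full((nc, nc), np.nan)
    max_diff = np.zeros((nc, nc), dtype=float)
    mean_dist = np.full((nc, nc), np.nan)
    mean_diff = np.full((nc, nc), np.nan)
    for a, ca in enumerate(clades):
        for b, cb in enumerate(clades):
            if a == b:
                continue
            block_d = dm.dist[np.ix_(idx[ca], idx[cb])]
            block_n = dm.diff[np.ix_(idx[ca], idx[cb])]
            min_dist[a, b] = block_d.min()
            max_diff[a, b] = block_n.max()
            mean_dist[a, b] = block_d.mean()
            mean_diff[a, b] = block_n.mean()
    rows = []
    for c in clades:
        ii = idx[c]
        if len(ii) < 2:
            rows.append(
                {"clade": c, "n_taxa": len(ii), "dist_min": 0.0, "dist_max": 0.0,
                 "diff_min": 0, "diff_max": 0}
            )
            continue
        iu = np.triu_indices(len(ii), k=1)
        d = dm.dist[np.ix_(ii, ii)][iu]
        nn = dm.diff[np.ix_(ii, ii)][iu]
        rows.append(
            {"clade": c, "n_taxa": len(ii),
             "dist_min": float(d.min()), "dist_max": float(d.max()),
             "diff_min": int(nn.min()), "diff_max": int(nn.max())}
        )
    mk = lambda arr: pd.DataFrame(arr, index=clades, columns=clades)
    return CladeDistanceSummary(
        clades=clades,
        min_dist=mk(min_dist),
        max_diff=mk(max_diff),
        mean_dist=mk(mean_dist),
        mean_diff=mk(mean_diff),
        within=pd.DataFrame(rows),
    )


def half_matrix_report(
    summary: CladeDistanceSummary, path: str | Path, decimal: str = "."
) -> None:
    """Write the combined half-matrix: min %-distance upper right, max nt
    difference lower left, '-' on the diagonal.  ``decimal=','`` switches
    to comma decimals."""
    clades = summary.clades
    with open(path, "w") as fh:
        fh.write("clade\t" + "\t".join(clades) + "\n")
        for a, ca in enumerate(clades):
            cells = []
            for b in range(len(clades)):
                if a == b:
                    cells.append("-")
                elif b > a:
                    v = f"{summary.min_dist.iat[a, b]:.2f}"
                    cells.append(v.replace(".", decimal) if decimal != "." else v)
                else:
                    cells.append(str(int(summary.max_diff.iat[a, b])))
            fh.write(ca + "\t" + "\t".join(cells) + "\n")
        fh.write("within_dist\t" + "\t".join(
            f"{r.dist_min:.2f}-{r.dist_max:.2f}".replace(".", decimal)
            if decimal != "." else f"{r.dist_min:.2f}-{r.dist_max:.2f}"
            for r in summary.within.itertuples()
        ) + "\n")
        fh.write("within_diff\t" + "\t".join(
            f"{r.diff_min}-{r.diff_max}" for r in summary.within.itertuples()
        ) + "\n")
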