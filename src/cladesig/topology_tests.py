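"""Tree-topology tests from site-wise log-likelihood matrices.

Given a [trees x sites] matrix of per-site log-likelihoods (as produced by
ML programs and consumed by CONSEL), this module implements the classical
resampling tests without re-optimising any tree:

* RELL bootstrap — resample site columns with replacement (one shared
  index vector per replicate across trees) and sum the stored per-site
  log-likelihoods.
* KH — one-sided Kishino-Hasegawa test for a pair of trees from
  mean-centered RELL replicates of the log-likelihood difference.
* SH / WSH — Shimodaira-Hasegawa test (plain and weighted) with
  per-tree centering and a max over competitors; the weighted variant
  standardises each pairwise difference by its RELL standard deviation.
* AU — approximately unbiased test via the multiscale bootstrap: naive
  bootstrap proportions BP(r) at several scale factors r are fitted with
  z(r) = d*sqrt(r) + c/sqrt(r) on the probit scale by weighted least
  squares, and p_AU = 1 - Phi(d - c).

All tests are deterministic for a fixed seed.  KH, SH and WSH computed
with the same seed share the same resampling replicates, so the algebraic
relations between them (e.g. SH at two trees equals max-centered KH) hold
exactly, not just in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import SitelhParseError


@dataclass
class SitewiseLnL:
    """Per-site log-likelihoods for a set of trees on one alignment."""

    tree_ids: list[str]
    L: np.ndarray  # shape (n_trees, n_sites)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2 or self.L.shape[0] != len(self.tree_ids):
            raise SitelhParseError(
                f"matrix shape {self.L.shape} does not match "
                f"{len(self.tree_ids)} tree ids"
            )
        if not np.isfinite(self.L).all():
            raise SitelhParseError("non-finite site log-likelihoods")

    @property
    def n_trees(self) -> int:
        return self.L.shape[0]

    @property
    def n_sites(self) -> int:
        return self.L.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.L.sum(axis=1)


def read_sitelh(path: str | Path) -> SitewiseLnL:
    """Read a TREE-PUZZLE-style ``.sitelh`` file.

    First line: "<n_trees> <n_sites>"; then one row per tree:
    "<tree_id> <lnL_1> ... <lnL_n>".
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise SitelhParseError(f"empty sitelh file {path}")
    head = lines[0].split()
    try:
        n_trees, n_sites = int(head[0]), int(head[1])
    except (ValueError, IndexError):
        raise SitelhParseError(f"bad sitelh header {lines[0]!r}") from None
    rows = lines[1:]
    if len(rows) != n_trees:
        raise SitelhParseError(f"header says {n_trees} trees, found {len(rows)} rows")
    ids: list[str] = []
    mat = np.empty((n_trees, n_sites))
    for k, row in enumerate(rows):
        parts = row.split()
        if len(parts) != n_sites + 1:
            raise SitelhParseError(
                f"row {k + 1}: expected {n_sites} values, found {len(parts) - 1}"
            )
        ids.append(parts[0])
        try:
            mat[k] = [float(v) for v in parts[1:]]
        except ValueError:
            raise SitelhParseError(f"non-numeric value in row {k + 1}") from None
    return SitewiseLnL(tree_ids=ids, L=mat)


def write_sitelh(S: SitewiseLnL, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{S.n_trees} {S.n_sites}\n")
        for tid, row in zip(S.tree_ids, S.L):
            fh.write(tid + " " + " ".join(f"{v:.10g}" for v in row) + "\n")


def rell_bootstrap(
    S: SitewiseLnL, B: int, seed: int, scale: float = 1.0
) -> np.ndarray:
    """RELL-resampled total log-likelihoods, shape (n_trees, B).

    Each replicate draws round(n_sites * scale) site indices with
    replacement; the same index vector is applied to every tree.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = S.n_sites
    m = max(1, int(round(n * scale)))
    totals = np.empty((S.n_trees, B))
    # chunk replicates to bound the index-matrix memory
    chunk = max(1, min(B, int(2e7 // m)))
    pos = 0
    while pos < B:
        k = min(chunk, B - pos)
        idx = rng.integers(0, n, size=(k, m))
        for t in range(S.n_trees):
            totals[t, pos : pos + k] = S.L[t][idx].sum(axis=1)
        pos += k
    return totals


def kh_test(
    S: SitewiseLnL,
    tree_i: int,
    tree_j: int,
    B: int = 10000,
    seed: int = 0,
    two_sided: bool = False,
    replicates: np.ndarray | None = None,
) -> float:
    """One-sided KH p-value for the worse of trees i and j.

    The observed difference d = lnL_i - lnL_j is compared with RELL
    replicate differences centered at their mean.  The one-sided p is the
    fraction of centered replicates that exceed |d| *in the direction of
    the better tree* (the p-value reported for the worse tree, matching
    the convention of RELL-based test software); under the null the
    two-sided variant (``two_sided=True``, twice-folded) is uniform.
    Pass ``replicates`` (from :func:`rell_bootstrap`) to share resampling
    with other tests.
    """
    if tree_i == tree_j:
        raise ValueError("tree_i and tree_j must differ")
    R = rell_bootstrap(S, B, seed) if replicates is None else replicates
    d_obs = float(S.totals[tree_i] - S.totals[tree_j])
    d_rep = R[tree_i] - R[tree_j]
    centered = d_rep - d_rep.mean()
    if two_sided:
        return float(np.mean(np.abs(centered) >= abs(d_obs)))
    if d_obs < 0:
        centered = -centered
    return float(np.mean(centered >= abs(d_obs)))


def sh_test(
    S: SitewiseLnL,
    B: int = 10000,
    seed: int = 0,
    replicates: np.ndarray | None = None,
) -> np.ndarray:
    """SH p-value per tree.

    For tree a the observed statistic is T_a = max_b lnL_b - lnL_a; the
    null distribution is built from per-tree mean-centered RELL replicates
    via T*_a = max_b centered_b - centered_a, and p_a is the fraction of
    replicates with T*_a >= T_a.
    """
    if S.n_trees < 2:
        raise ValueError("SH test needs at least 2 trees")
    R = rell_bootstrap(S, B, seed) if replicates is None else replicates
    totals = S.totals
    T_obs = totals.max() - totals
    C = R - R.mean(axis=1, keepdims=True)
    T_rep = C.max(axis=0, keepdims=True) - C
    return (T_rep >= T_obs[:, None]).mean(axis=1)


def wsh_test(
    S: SitewiseLnL,
    B: int = 10000,
    seed: int = 0,
    replicates: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted SH p-value per tree.

    As :func:`sh_test`, but every pairwise log-likelihood difference is
    standardised by its RELL standard deviation before the max; a
    zero-variance difference is defined to contribute 0.
    """
    if S.n_trees < 2:
        raise ValueError("WSH test needs at least 2 trees")
    R = rell_bootstrap(S, B, seed) if replicates is None else replicates
    totals = S.totals
    C = R - R.mean(axis=1, keepdims=True)
    K = S.n_trees
    sd = np.empty((K, K))
    for a in range(K):
        sd[a] = (C - C[a]).std(axis=1)
    p = np.empty(K)
    for a in range(K):
        s = sd[a].copy()
        s[s == 0] = np.inf  # zero-variance pair -> standardized statistic 0
        T_obs = np.max((totals - totals[a]) / s)
        T_rep = ((C - C[a]) / s[:, None]).max(axis=0)
        p[a] = np.mean(T_rep >= T_obs)
    return p


DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


def au_fit(
    bp: np.ndarray, scales: np.ndarray, B: int
) -> tuple[float, float, float, bool]:
    """Fit the multiscale signed-distance model to bootstrap proportions.

    Probit-transformed z(r) = Phi^-1(1 - BP(r)) is fitted with
    z(r) = d*sqrt(r) + c/sqrt(r) by weighted least squares (binomial
    delta-method weights); returns (p_AU, d, c, degenerate) with
    p_AU = 1 - Phi(d - c).  BP values are clamped to
    [1/(2B), 1 - 1/(2B)] so the probit stays finite; if every BP clamps to
    the same side the fit is degenerate and p is 0 or 1 with a flag.
    """
    bp = np.asarray(bp, dtype=float)
    scales = np.asarray(scales, dtype=float)
    eps = 1.0 / (2.0 * B)
    clamped = np.clip(bp, eps, 1.0 - eps)
    if np.all(bp <= eps):
        return 0.0, np.nan, np.nan, True
    if np.all(bp >= 1.0 - eps):
        return 1.0, np.nan, np.nan, True
    z = norm.ppf(1.0 - clamped)
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    w = B * norm.pdf(z) ** 2 / (clamped * (1.0 - clamped))
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
    d, c = float(coef[0]), float(coef[1])
    return float(1.0 - norm.cdf(d - c)), d, c, False


def au_test(
    S: SitewiseLnL,
    B_per_scale: int = 10000,
    scales: tuple[float, ...] = DEFAULT_AU_SCALES,
    seed: int = 0,
) -> tuple[np.ndarray, list[bool]]:
    """AU p-value per tree via the multiscale bootstrap.

    At each scale r, ``B_per_scale`` RELL replicates of round(n*r) sites
    yield BP(r), the proportion of replicates in which the tree attains
    the maximum total; :func:`au_fit` turns the BP curve into p_AU.

    Returns (p array, degeneracy flags).
    """
    scales_arr = np.asarray(scales, dtype=float)
    if scales_arr.size < 2 or not (scales_arr.min() < 1.0 < scales_arr.max()):
        raise ValueError("scales must span values below and above 1")
    K = S.n_trees
    bps = np.empty((K, scales_arr.size))
    for si, r in enumerate(scales_arr):
        R = rell_bootstrap(S, B_per_scale, seed + si, scale=float(r))
        winner = R.argmax(axis=0)
        for t in range(K):
            bps[t, si] = np.mean(winner == t)
    p = np.empty(K)
    flags: list[bool] = []
    for t in range(K):
        p[t], _, _, degen = au_fit(bps[t], scales_arr, B_per_scale)
        flags.append(degen)
    return p, flags


def topology_report(
    S: SitewiseLnL,
    tests: tuple[str, ...] = ("kh", "sh", "wsh", "au"),
    B: int = 10000,
    au_scales: tuple[float, ...] = DEFAULT_AU_SCALES,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per tree: total lnL, delta to best, requested p-values and a
    significance marker for trees worse than the best at ``alpha``.

    KH p-values are computed against the best tree (ties for best broken
    by input order and flagged in the ``best_tie`` column).
    """
    totals = S.totals
    best = int(np.argmax(totals))
    tie = bool(np.sum(totals == totals[best]) > 1)
    out = pd.DataFrame(
        {
            "tree": S.tree_ids,
            "lnL": totals,
            "delta": totals[best] - totals,
        }
    )
    R = rell_bootstrap(S, B, seed)
    if "kh" in tests:
        out["p_KH"] = [
            1.0 if t == best else kh_test(S, best, t, B=B, seed=seed, replicates=R)
            for t in range(S.n_trees)
        ]
    if "sh" in tests:
        out["p_SH"] = sh_test(S, B=B, seed=seed, replicates=R)
    if "wsh" in tests:
        out["p_WSH"] = wsh_test(S, B=B, seed=seed, replicates=R)
    if "au" in tests:
        p_au, flags = au_test(S, B_per_scale=B, scales=au_scales, seed=seed)
        out["p_AU"] = p_au
        out["au_degenerate"] = flags
    pcols = [c for c in out.columns if c.startswith("p_")]
    out["significantly_worse"] = (out[pcols] <= alpha).all(axis=1) & (
        out.index != best
    )
    out["best_tie"] = tie
    out.attrs["B"] = B
    out.attrs["au_scales"] = tuple(au_scales)
    out.attrs["seed"] = seed
    return out
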