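"""Synthetic alignments and site-likelihoods with planted ground truth.

This module makes every pipeline stage exercisable without downloading
sequence data.  It provides:

* a GTR+I+G sequence evolver over a newick tree (root drawn from the
  stationary frequencies, discrete-gamma rate heterogeneity with a
  proportion of invariable sites, rate matrix normalised so one unit of
  branch length is one expected substitution per site for the mixture);
* planting operators that write clade-diagnostic columns (optionally as
  compensatory pairs on structurally paired columns) and an intron-style
  gap block into the simulated alignment, recording every planted feature
  in a ground-truth ledger;
* Felsenstein-pruning site-wise log-likelihoods for a tree and model, the
  standard input of the topology tests; and
* a direct generator of site-wise log-likelihood matrices
  (base + per-tree offset + noise) for calibrating the topology tests
  under exchangeable nulls and known alternatives.

Default model parameters emulate an SSU rDNA data set of a fast-evolving
filamentous green-algal genus: GTR exchangeabilities
(AC 1.4341, AG 2.6641, AT 1.2357, CG 1.6993, CT 5.2526, GT 1), base
frequencies (A .2338, C .2439, G .2871, T .2351), invariable proportion
I = 0.6009 and gamma shape 0.6856.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from .errors import PlantSpecError, TaxaError
from .seq_data import BASES, IUPAC_EXPAND, AlignedSeqSet
from .structure_map import classify_pair_change
from .topology_tests import SitewiseLnL

#: sentinel for a zero site likelihood (log-likelihood of -inf)
SENTINEL_LNL = -1.0e9


@dataclass(frozen=True)
class ModelParams:
    """GTR+I+G substitution-model parameters.

    Exchangeabilities are relative to r_GT = 1; ``gamma_shape=None``
    disables rate heterogeneity (single rate class).
    """

    r_ac: float = 1.0
    r_ag: float = 1.0
    r_at: float = 1.0
    r_cg: float = 1.0
    r_ct: float = 1.0
    r_gt: float = 1.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.0
    gamma_shape: float | None = None
    n_cat: int = 4

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        # published tables round to 4 decimals; renormalise near-1 sums
        if f.shape != (4,) or (f <= 0).any() or abs(f.sum() - 1.0) > 1e-3:
            raise ValueError("base frequencies must be positive and sum to 1")
        object.__setattr__(self, "freqs", tuple(f / f.sum()))
        rates = (self.r_ac, self.r_ag, self.r_at, self.r_cg, self.r_ct, self.r_gt)
        if any(r <= 0 for r in rates):
            raise ValueError("exchangeabilities must be positive")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_cat < 1:
            raise ValueError("n_cat must be >= 1")

    @classmethod
    def jc(cls, p_inv: float = 0.0, gamma_shape: float | None = None) -> "ModelParams":
        """Jukes-Cantor: equal frequencies, equal exchangeabilities."""
        return cls(p_inv=p_inv, gamma_shape=gamma_shape)

    @classmethod
    def ssu_gtr_ig(cls) -> "ModelParams":
        """GTR+I+G defaults for the fast-evolving genus SSU alignment."""
        return cls(
            r_ac=1.4341, r_ag=2.6641, r_at=1.2357, r_cg=1.6993, r_ct=5.2526,
            r_gt=1.0, freqs=(0.2338, 0.2439, 0.2871, 0.2351),
            p_inv=0.6009, gamma_shape=0.6856,
        )

    @classmethod
    def zygnematophyceae_ssu(cls) -> "ModelParams":
        """TrN+I+G fit of the family-level SSU alignment, expressed as GTR
        with tied exchangeabilities (r_AC = r_AT = r_CG = r_GT = 1)."""
        return cls(
            r_ac=1.0, r_ag=1.8721, r_at=1.0, r_cg=1.0, r_ct=4.5252, r_gt=1.0,
            freqs=(0.2545, 0.2280, 0.2665, 0.2510),
            p_inv=0.4608, gamma_shape=0.6376,
        )


def rate_matrix(params: ModelParams) -> np.ndarray:
    """GTR rate matrix, normalised to one expected substitution per unit time."""
    pi = np.asarray(params.freqs)
    r = np.zeros((4, 4))
    pairs = {
        (0, 1): params.r_ac, (0, 2): params.r_ag, (0, 3): params.r_at,
        (1, 2): params.r_cg, (1, 3): params.r_ct, (2, 3): params.r_gt,
    }
    for (i, j), v in pairs.items():
        r[i, j] = r[j, i] = v
    Q = r * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def gamma_category_rates(shape: float, n_cat: int) -> np.ndarray:
    """Discrete-gamma category rates, median method, normalised to mean 1."""
    q = (2.0 * np.arange(n_cat) + 1.0) / (2.0 * n_cat)
    rates = gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def mixture_rate_classes(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """(rates, weights) of the I+G mixture, overall expected rate 1.

    The invariable class has rate 0 and weight I; the variable classes
    carry gamma-category rates scaled by 1/(1-I) so the mixture mean is 1.
    """
    if params.gamma_shape is None:
        var_rates = np.array([1.0])
    else:
        var_rates = gamma_category_rates(params.gamma_shape, params.n_cat)
    k = var_rates.size
    if params.p_inv > 0:
        rates = np.concatenate([[0.0], var_rates / (1.0 - params.p_inv)])
        weights = np.concatenate(
            [[params.p_inv], np.full(k, (1.0 - params.p_inv) / k)]
        )
    else:
        rates = var_rates
        weights = np.full(k, 1.0 / k)
    return rates, weights


class GTREigen:
    """Eigendecomposition of a reversible rate matrix for fast P(t)."""

    def __init__(self, params: ModelParams):
        self.pi = np.asarray(params.freqs)
        Q = rate_matrix(params)
        sq = np.sqrt(self.pi)
        S = (Q * sq[:, None]) / sq[None, :]
        S = (S + S.T) / 2.0  # exact symmetry
        lam, U = np.linalg.eigh(S)
        self._lam = lam
        self._left = U / sq[:, None] * 1.0
        self._right = (U * sq[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t == 0.0:
            return np.eye(4)
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# planting specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedNHS:
    """One clade-diagnostic column to write into a simulated alignment.

    ``outside_state=None`` only rewrites outside occurrences of
    ``state_in`` (to the next base cyclically); giving an explicit base
    writes it to *all* outside taxa, which pins the outside consensus and
    makes the expected CBC class of a planted pair deterministic.
    """

    clade: str
    column: int              # 1-based
    state_in: str
    outside_state: str | None = None
    partner_column: int | None = None
    partner_state_in: str | None = None
    partner_outside_state: str | None = None


@dataclass(frozen=True)
class IntronPlant:
    """Gap block emulating an intron: carriers keep simulated bases, all
    other taxa get gaps across the block."""

    carriers: frozenset[str]
    start: int               # 1-based
    length: int


@dataclass
class SimConfig:
    """Full specification of one synthetic data set."""

    newick: str
    params: ModelParams
    n_sites: int
    seed: int
    clade_of: dict[str, str] | None = None
    planted_nhs: list[PlantedNHS] = field(default_factory=list)
    intron: IntronPlant | None = None
    homoplasy_rate: float = 0.0


def _parse_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        return dendropy.Tree.get(
            data=tree, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TaxaError(f"cannot parse newick tree: {exc}") from exc


def _sample_states(P: np.ndarray, parent: np.ndarray, u: np.ndarray) -> np.ndarray:
    cum = P.cumsum(axis=1)
    return (cum[parent] < u[:, None]).sum(axis=1).astype(np.int8)


def simulate_alignment(cfg: SimConfig) -> tuple[AlignedSeqSet, pd.DataFrame]:
    """Evolve sequences along the tree, then apply planting operators.

    Returns the alignment (clade labels attached when given) and a
    ground-truth ledger with one row per planted feature (kind
    ``nhs``/``cbc_pair``/``intron``), including the expected CBC class of
    planted pairs and whether homoplasy injection broke a planted column.
    """
    tree = _parse_tree(cfg.newick)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    eig = GTREigen(cfg.params)
    rates, weights = mixture_rate_classes(cfg.params)
    site_class = rng.choice(rates.size, size=n, p=weights)
    site_rate = rates[site_class]

    root = tree.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.choice(4, size=n, p=np.asarray(cfg.params.freqs))
    }
    unique_rates = np.unique(site_rate)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_states = states[id(node.parent_node)]
        child = parent_states.copy()
        if t > 0:
            for r in unique_rates:
                if r == 0:
                    continue
                idx = np.flatnonzero(site_rate == r)
                if idx.size == 0:
                    continue
                P = eig.transition(t * r)
                u = rng.random(idx.size)
                child[idx] = _sample_states(P, parent_states[idx], u)
        states[id(node)] = child

    base_arr = np.array(list(BASES))
    ids, seqs = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        seqs.append(base_arr[states[id(leaf)]])
    order = np.argsort(ids, kind="stable")
    ids = [ids[k] for k in order]
    rows = [seqs[k] for k in order]
    mat = np.stack(rows)

    ledger_rows: list[dict] = []

    if cfg.intron is not None:
        iv = cfg.intron
        if not (1 <= iv.start and iv.start + iv.length - 1 <= n):
            raise PlantSpecError("intron block outside alignment bounds")
        unknown = iv.carriers - set(ids)
        if unknown:
            raise PlantSpecError(f"intron carriers not in tree: {sorted(unknown)}")
        block = slice(iv.start - 1, iv.start - 1 + iv.length)
        for k, tid in enumerate(ids):
            if tid not in iv.carriers:
                mat[k, block] = "-"
        ledger_rows.append(
            {"kind": "intron", "start": iv.start,
             "end": iv.start + iv.length - 1,
             "taxa": ",".join(sorted(iv.carriers))}
        )

    if cfg.planted_nhs:
        if cfg.clade_of is None:
            raise PlantSpecError("planted NHS require clade assignments")
        _plant_nhs_inplace(mat, ids, cfg, rng, ledger_rows)

    aln = AlignedSeqSet(
        ids=ids,
        seqs=["".join(r) for r in mat],
        clade_of=dict(cfg.clade_of) if cfg.clade_of else None,
    )
    return aln, pd.DataFrame(ledger_rows)


def _next_base(b: str) -> str:
    return BASES[(BASES.index(b) + 1) % 4]


def _plant_one(
    mat: np.ndarray, in_rows: np.ndarray, out_rows: np.ndarray,
    column: int, state_in: str, outside_state: str | None,
) -> None:
    c = column - 1
    mat[in_rows, c] = state_in
    if outside_state is not None:
        mat[out_rows, c] = outside_state
    else:
        hit = out_rows[mat[out_rows, c] == state_in]
        mat[hit, c] = _next_base(state_in)


def _plant_nhs_inplace(
    mat: np.ndarray, ids: list[str], cfg: SimConfig,
    rng: np.random.Generator, ledger_rows: list[dict],
) -> None:
    n = cfg.n_sites
    claimed: set[int] = set()
    intron_cols: set[int] = set()
    if cfg.intron is not None:
        intron_cols = set(
            range(cfg.intron.start, cfg.intron.start + cfg.intron.length)
        )
    for spec in cfg.planted_nhs:
        cols = [spec.column] + ([spec.partner_column] if spec.partner_column else [])
        for c in cols:
            if not 1 <= c <= n:
                raise PlantSpecError(f"planted column {c} outside 1..{n}")
            if c in claimed:
                raise PlantSpecError(f"planted columns overlap at {c}")
            if c in intron_cols:
                raise PlantSpecError(f"planted column {c} inside intron block")
            claimed.add(c)
        if spec.state_in not in BASES:
            raise PlantSpecError(f"bad inside state {spec.state_in!r}")
        if spec.outside_state == spec.state_in:
            raise PlantSpecError(
                f"outside state equals inside state at column {spec.column}"
            )
        members = [t for t, c in cfg.clade_of.items() if c == spec.clade]
        if not members:
            raise PlantSpecError(f"planted clade {spec.clade!r} has no taxa")
        member_set = set(members)
        in_rows = np.array(
            [k for k, t in enumerate(ids) if t in member_set], dtype=int
        )
        out_rows = np.array(
            [k for k, t in enumerate(ids) if t not in member_set], dtype=int
        )
        if out_rows.size == 0 and spec.outside_state is not None:
            raise PlantSpecError("no outside taxa to receive the outside state")

        _plant_one(mat, in_rows, out_rows, spec.column,
                   spec.state_in, spec.outside_state)
        broken = False
        if cfg.homoplasy_rate > 0 and out_rows.size and rng.random() < cfg.homoplasy_rate:
            victim = rng.choice(out_rows)
            mat[victim, spec.column - 1] = spec.state_in
            broken = True

        if spec.partner_column is None:
            ledger_rows.append(
                {"kind": "nhs", "clade": spec.clade, "column": spec.column,
                 "state_in": spec.state_in, "outside_state": spec.outside_state,
                 "broken": broken}
            )
            continue

        if spec.partner_state_in is None or spec.partner_outside_state is None \
                or spec.outside_state is None:
            raise PlantSpecError(
                "planted pairs need explicit inside and outside states on "
                "both columns"
            )
        _plant_one(mat, in_rows, out_rows, spec.partner_column,
                   spec.partner_state_in, spec.partner_outside_state)
        expected = classify_pair_change(
            (spec.outside_state, spec.partner_outside_state),
            (spec.state_in, spec.partner_state_in),
        )
        ledger_rows.append(
            {"kind": "cbc_pair", "clade": spec.clade, "column": spec.column,
             "partner_column": spec.partner_column,
             "state_in": spec.state_in, "outside_state": spec.outside_state,
             "partner_state_in": spec.partner_state_in,
             "partner_outside_state": spec.partner_outside_state,
             "expected_class": expected, "broken": broken}
        )


# ---------------------------------------------------------------------------
# site-wise log-likelihoods by pruning
# ---------------------------------------------------------------------------

def _leaf_partials(seq: str) -> np.ndarray:
    out = np.zeros((len(seq), 4))
    for i, ch in enumerate(seq):
        comp = IUPAC_EXPAND.get(ch, frozenset())
        if not comp:  # gap: missing data
            out[i] = 1.0
        else:
            for b in comp:
                out[i, BASES.index(b)] = 1.0
    return out


def sitewise_loglik(
    aln: AlignedSeqSet, tree: str | dendropy.Tree, params: ModelParams
) -> np.ndarray:
    """Per-site log-likelihoods by Felsenstein pruning under GTR+I+G.

    Gaps and ambiguity codes are treated as missing data (partial
    likelihood 1 over compatible states).  The mixture over the invariable
    class and the gamma categories is taken per site.  Sites with zero
    likelihood are reported as the sentinel :data:`SENTINEL_LNL`.
    """
    tree = _parse_tree(tree)
    leaf_taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = set(leaf_taxa) - set(aln.ids)
    if missing:
        raise TaxaError(f"tree taxa not in alignment: {sorted(missing)}")
    eig = GTREigen(params)
    rates, weights = mixture_rate_classes(params)
    n = aln.n_columns
    pi = np.asarray(params.freqs)

    leaf_parts = {t: _leaf_partials(aln.seq_of(t)) for t in leaf_taxa}
    lnl_classes = np.empty((rates.size, n))
    for ci, r in enumerate(rates):
        partial: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partial[id(node)] = leaf_parts[node.taxon.label]
                logscale[id(node)] = np.zeros(n)
                continue
            prod = np.ones((n, 4))
            ls = np.zeros(n)
            for child in node.child_nodes():
                t_edge = (child.edge.length or 0.0) * r
                P = eig.transition(t_edge)
                prod *= partial[id(child)] @ P.T
                ls += logscale[id(child)]
            m = prod.max(axis=1)
            nz = m > 0
            prod[nz] /= m[nz, None]
            with np.errstate(divide="ignore"):
                ls += np.where(nz, np.log(np.maximum(m, 1e-300)), -np.inf)
            partial[id(node)] = prod
            logscale[id(node)] = ls
        root = tree.seed_node
        site_l = partial[id(root)] @ pi
        with np.errstate(divide="ignore"):
            lnl_classes[ci] = np.log(site_l, where=site_l > 0,
                                     out=np.full(n, -np.inf)) + logscale[id(root)]
    with np.errstate(divide="ignore"):
        lnl = logsumexp(lnl_classes, axis=0, b=weights[:, None])
    return np.where(np.isneginf(lnl), SENTINEL_LNL, lnl)


def sitewise_loglik_matrix(
    aln: AlignedSeqSet,
    trees: Sequence[str | dendropy.Tree],
    params: ModelParams,
    tree_ids: Sequence[str] | None = None,
) -> SitewiseLnL:
    """Stack :func:`sitewise_loglik` rows for several trees."""
    ids = list(tree_ids) if tree_ids else [f"tree{k + 1}" for k in range(len(trees))]
    L = np.stack([sitewise_loglik(aln, t, params) for t in trees])
    return SitewiseLnL(tree_ids=ids, L=L)


def simulate_sitelh(
    n_trees: int,
    n_sites: int,
    offsets: Sequence[float] | None = None,
    noise_sd: float = 1.0,
    base_mean: float = -2.0,
    base_sd: float = 1.0,
    seed: int = 0,
) -> SitewiseLnL:
    """Direct site-lnL generator: base + per-tree offset + iid noise.

    With zero offsets the trees are exchangeable (a valid null for the
    topology tests); a positive offset for one tree makes it better by
    ``offset`` per site on average.
    """
    if n_trees < 2:
        raise ValueError("need at least 2 trees")
    rng = np.random.default_rng(seed)
    off = np.zeros(n_trees) if offsets is None else np.asarray(offsets, dtype=float)
    if off.shape != (n_trees,):
        raise ValueError("offsets must have one entry per tree")
    base = rng.normal(base_mean, base_sd, size=n_sites)
    noise = rng.normal(0.0, noise_sd, size=(n_trees, n_sites))
    L = base[None, :] + off[:, None] + noise
    return SitewiseLnL(tree_ids=[f"tree{k + 1}" for k in range(n_trees)], L=L)


# ---------------------------------------------------------------------------
# study-shaped configuration
# ---------------------------------------------------------------------------

STUDY_CLADES = tuple("ABCDEFGH")


def study_tree(
    n_per_clade: int = 3,
    n_outgroup: int = 4,
    seed: int = 0,
) -> tuple[str, dict[str, str]]:
    """A clade-structured newick tree emulating the study's taxon layout.

    Eight ingroup clades (A..H, ``n_per_clade`` taxa each) hang off a
    genus stem, with ``n_outgroup`` outgroup taxa (clade label ``Z``).
    Branch lengths: short within clades (~0.01-0.02), longer clade stems
    (~0.06-0.14), jittered deterministically by ``seed``.

    Returns (newick, taxon -> clade label).
    """
    rng = np.random.default_rng(seed)
    clade_of: dict[str, str] = {}
    clade_strs = []
    for clade in STUDY_CLADES:
        tips = []
        for k in range(1, n_per_clade + 1):
            name = f"{clade}{k}"
            clade_of[name] = clade
            tips.append(f"{name}:{rng.uniform(0.005, 0.02):.5f}")
        stem = rng.uniform(0.06, 0.14)
        clade_strs.append(f"({','.join(tips)}):{stem:.5f}")
    genus = f"({','.join(clade_strs)}):0.10000"
    out_tips = []
    for k in range(1, n_outgroup + 1):
        name = f"Z{k}"
        clade_of[name] = "Z"
        out_tips.append(f"{name}:{rng.uniform(0.03, 0.08):.5f}")
    outgroup = f"({','.join(out_tips)}):0.10000"
    return f"({genus},{outgroup});", clade_of


def study_config(
    seed: int,
    n_sites: int = 1700,
    n_per_clade: int = 3,
    n_outgroup: int = 4,
    intron_length: int = 130,
    n_planted_per_clade: int = 2,
    n_planted_pairs_per_clade: int = 1,
    homoplasy_rate: float = 0.0,
) -> SimConfig:
    """A full study-shaped simulation config.

    1700 sites under the genus GTR+I+G fit, an intron-style 130-column
    gap block carried by clades A-D (secondarily lost in E-H and absent
    in the outgroup), ``n_planted_per_clade`` single diagnostic columns
    and ``n_planted_pairs_per_clade`` diagnostic base pairs per ingroup
    clade, all planted after the intron block.  Planted pairs alternate
    CBC (outside C-G, inside T-A) and hemi-CBC (outside C-G, inside T-G)
    by clade.
    """
    newick, clade_of = study_tree(n_per_clade, n_outgroup, seed)
    rng = np.random.default_rng(seed + 1)
    carriers = frozenset(
        t for t, c in clade_of.items() if c in ("A", "B", "C", "D")
    )
    n_cols = (n_planted_per_clade + 2 * n_planted_pairs_per_clade) * len(STUDY_CLADES)
    reserve = max(200, 3 * n_cols)  # planting zone at the alignment tail
    intron_start = n_sites - reserve - intron_length + 1
    if intron_start < 1:
        raise PlantSpecError(
            f"n_sites={n_sites} too small for a {intron_length}-column intron "
            f"block plus a {reserve}-column planting zone"
        )
    intron = IntronPlant(carriers=carriers, start=intron_start,
                         length=intron_length)
    plant_zone = list(range(intron_start + intron_length, n_sites + 1))
    cols = iter(rng.choice(plant_zone, size=n_cols, replace=False))
    planted = []
    for ci, clade in enumerate(STUDY_CLADES):
        for _ in range(n_planted_per_clade):
            state_in = BASES[rng.integers(0, 4)]
            planted.append(
                PlantedNHS(
                    clade=clade, column=int(next(cols)), state_in=state_in,
                    outside_state=_next_base(state_in),
                )
            )
        for _ in range(n_planted_pairs_per_clade):
            inside = ("T", "A") if ci % 2 == 0 else ("T", "G")  # CBC vs HCBC
            planted.append(
                PlantedNHS(
                    clade=clade, column=int(next(cols)), state_in=inside[0],
                    outside_state="C", partner_column=int(next(cols)),
                    partner_state_in=inside[1], partner_outside_state="G",
                )
            )
    return SimConfig(
        newick=newick, params=ModelParams.ssu_gtr_ig(), n_sites=n_sites,
        seed=seed, clade_of=clade_of, planted_nhs=planted, intron=intron,
        homoplasy_rate=homoplasy_rate,
    )


def evaluate_planted_recovery(
    aln: AlignedSeqSet,
    ledger: pd.DataFrame,
    cfg: SimConfig,
) -> dict[str, float]:
    """Score the NHS scanner against a config's planted ground truth.

    Runs the scanner per planted clade (with the planted pairing map) and
    scores it over the planted columns:

    * recall — fraction of unbroken planted diagnostic columns reported
      as NHS with the planted inside state;
    * precision — fraction of scanner records at planted columns that
      match the planted state (and, for planted pairs, the expected
      CBC/HCBC class); a record at a homoplasy-broken column counts
      against precision;
    * class_accuracy — fraction of unbroken planted pairs whose reported
      class equals the ledger's expected class.

    Background diagnostics arising from the substitution process itself
    are not scanner errors and are excluded; the scanner's exactness on
    full columns is covered by the brute-force oracle instead.
    """
    from .nhs_scan import CladePartition, find_nhs

    partition = CladePartition(clade_of=dict(cfg.clade_of))
    pm = planted_pairing_map(cfg)
    planted = ledger[ledger["kind"].isin(["nhs", "cbc_pair"])]
    by_clade: dict[str, pd.DataFrame] = dict(tuple(planted.groupby("clade")))
    n_expected = n_recalled = 0
    n_reported = n_correct = 0
    n_pairs = n_class_ok = 0
    for clade, feats in by_clade.items():
        recs = {r.column: r for r in find_nhs(aln, partition, (clade,), pm)}
        for row in feats.itertuples():
            broken = bool(getattr(row, "broken", False))
            expected_class = (
                row.expected_class if row.kind == "cbc_pair" else None
            )
            # main column: injected homoplasy must make the scanner drop it
            rec = recs.get(int(row.column))
            if broken:
                if rec is not None:
                    n_reported += 1  # reporting a broken column: precision hit
            else:
                n_expected += 1
                if rec is not None and rec.state_in == row.state_in:
                    n_recalled += 1
                if rec is not None:
                    n_reported += 1
                    ok = rec.state_in == row.state_in
                    if ok and expected_class is not None:
                        ok = rec.cbc_class == expected_class
                    n_correct += ok
            # CBC partner column: an NHS in its own right, broken or not
            if expected_class == "CBC":
                prec = recs.get(int(row.partner_column))
                n_expected += 1
                if prec is not None and prec.state_in == row.partner_state_in:
                    n_recalled += 1
                if prec is not None:
                    n_reported += 1
                    n_correct += prec.state_in == row.partner_state_in
            if expected_class is not None and not broken:
                n_pairs += 1
                if rec is not None and rec.cbc_class == expected_class:
                    n_class_ok += 1
    return {
        "recall": n_recalled / n_expected if n_expected else 1.0,
        "precision": n_correct / n_reported if n_reported else 1.0,
        "class_accuracy": n_class_ok / n_pairs if n_pairs else 1.0,
    }


def planted_pairing_map(cfg: SimConfig) -> "PairingMap":
    """Pairing map over the planted partner columns of a config."""
    from .structure_map import PairingMap

    pairs = {
        (min(s.column, s.partner_column), max(s.column, s.partner_column))
        for s in cfg.planted_nhs
        if s.partner_column is not None
    }
    return PairingMap(pairs=pairs)
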