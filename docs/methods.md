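# Methods

This note documents the models and conventions implemented in `cladesig`,
the parameters that matter, and the design choices made where the
underlying methodology leaves room.

## Alignment handling and masking

All statistics operate on an aligned set of IUPAC DNA sequences with a
boolean column mask. Input is normalised on read: uppercase, U→T, '.'→'-';
any character outside `{A,C,G,T, R,Y,S,W,K,M,B,D,H,V,N, -}` is an error.
Coordinates in every report are 1-based alignment columns.

Published SSU analyses restrict themselves to "unambiguously aligned"
regions chosen by hand. We define the mask algorithmically — a column is
included iff its gap fraction and its ambiguity-code fraction are each at
most a threshold (defaults 0.05 / 0.05) — and additionally accept an
explicit list of included columns, so a manually curated mask can be
reproduced exactly. The mask is monotone in the thresholds by
construction.

Clone deduplication compares full gap-stripped normalised sequences, not
masked columns, because clones are collapsed before masking in the
standard workflow; a masked-columns mode is exposed for sensitivity
analysis. The representative of a sequence type is its lexicographically
smallest member id.

## NHS scanning

A mask-included column is a non-homoplasious synapomorphy (NHS) for a
target set of clades iff

1. every target taxon carries the same unambiguous base x (strict
   conservation), and
2. no taxon outside the target carries x (absence of convergence).

Gap/ambiguity policy (chosen to avoid false positives): a gap or
ambiguity code inside the target rejects the column; a gap outside
neither matches nor blocks (a gap is not state x); an ambiguity code
outside whose IUPAC expansion contains x counts as convergence and
rejects the column. NHS records are numbered in column order per run —
ordinal numbering of a published table is generally not reconstructible,
so no attempt is made to match one.

The scanner is vectorised over columns; its reference semantics are fixed
by an independent naive double-loop oracle that the test suite and the
acceptance script run against thousands of random alignments.

## CBC / HCBC annotation

Canonical pairing is Watson–Crick plus the G·T (G·U) wobble — the
standard rRNA covariation convention; whether wobble retention counts as
pairing is configurable only in the sense that each pair's class is
reported, so either tally can be formed downstream.

For an NHS at column i whose structural partner is column j, the pair
change (consensus-outside_i, consensus-outside_j) → (inside_i, inside_j)
is classified as

* **CBC** — both positions changed and both the before and the after
  state pair;
* **HCBC** — exactly one position changed, pairing retained;
* **break** — the after state does not pair;
* **none / indeterminate** — no change, pairing gained where the before
  state did not pair, or gaps/ambiguity prevent a call.

When both ends of a pair are NHS for the same target, the inside state
necessarily differs from the outside consensus at both ends, so that
configuration can only yield CBC or break. A hemi-CBC therefore arises
when one partner is diagnostic and the other is merely strictly conserved
inside the clade; the conserved partner's uniform inside base is used as
the after state. Consensus-outside is the majority unambiguous base among
non-target taxa; ties are broken alphabetically and flagged. Pairs with a
partner on a mask-excluded column are retained but flagged and left
unclassified. Shared indels are never treated as NHS states.

## Distances

The pairwise difference between two taxa counts masked columns where both
carry unambiguous, differing bases. The percent distance divides by the
total masked-column count (the fixed "aligned bases" denominator of the
classic workflow), so `dist = 100 · diff / denominator` holds exactly in
rational arithmetic; a pairwise-comparable denominator is available
behind a flag. Clade summaries report, per clade pair, the minimum
percent distance and the maximum nucleotide difference (the two halves of
the conventional half-matrix) along with means and per-clade min–max
ranges; a singleton clade's within range is 0–0.

## Relative-rate test

For ingroup sequences a, b and an outgroup sequence, over masked columns
where all three are unambiguous,

    n_a = #{a≠b, b=og},  n_b = #{a≠b, a=og},
    chi2 = (n_a − n_b)² / (n_a + n_b),  df = 1,

with p the upper-tail chi-square probability (Tajima's 1993 1D test, the
statistic implemented by the GRate-style tools this replaces). With no
informative site the test is degenerate (chi2 = 0, p = 1). Stars follow
the conventional thresholds: p > 0.05 N.S.; (0.01, 0.05] \*;
(0.005, 0.01] \*\*; ≤ 0.005 \*\*\*.

Group-level matrices run every cross-group taxon pair against every
outgroup taxon and print, per group pair, the star class of the
median-chi-square pair (lower median); the full per-pair detail table is
always exported, since a single symbol per cell necessarily hides the
spread.

Calibration: the null simulation used by the tests is a three-taxon
Jukes–Cantor star with tip branches 0.1 and outgroup branch 0.2
(1645 sites). These lengths were chosen by computing the test's exact
unconditional rejection probability under the null (mixing the
conditional binomial distribution of n_a given n_a+n_b over the
multinomial distribution of informative-site counts): at these lengths
the exact level is 0.0500, and the discreteness of small-count chi-square
tests is negligible. The empirical check uses 2000 replicates, whose 95%
binomial band around 0.05 is [0.0405, 0.0595].

## Topology tests

Input is a trees × sites matrix of per-site log-likelihoods (TREE-PUZZLE
`.sitelh` dialect or TSV), produced upstream by an ML program; tree
search and likelihood optimisation are outside this package's scope.

* **RELL bootstrap** — each replicate draws `round(n·scale)` site indices
  with replacement and sums stored per-site values; one shared index
  vector per replicate across trees (the RELL requirement). Deterministic
  for a fixed seed; replicates can be shared across tests so algebraic
  relations hold exactly rather than in distribution.
* **KH** — observed d = lnL_i − lnL_j; replicates centered at their mean;
  the one-sided p (reported for the worse tree, the convention of
  CONSEL-style software) is the fraction of centered replicates exceeding
  |d| in the better tree's direction. Because the worse tree is selected
  post hoc, the one-sided null p is uniform on (0, ½); the two-sided
  variant (behind a flag) is uniform on (0, 1) and is what the
  null-uniformity test checks.
* **SH** — T_a = max_b lnL_b − lnL_a; replicate statistics use per-tree
  mean-centered totals with the max over competitors; p_a is the fraction
  of replicates with T\*_a ≥ T_a. With two trees this reduces exactly to
  the max-centered KH p on the same replicates, and adding a dominated
  tree can only raise p (both are asserted exactly, same seed).
* **WSH** — as SH with every pairwise difference standardised by its RELL
  standard deviation before the max; a zero-variance difference
  contributes 0. The statistic is invariant to rescaling all site values.
* **AU** — at scales r ∈ {0.5, …, 1.4} (step 0.1, 10⁴ replicates per
  scale by default) the naive bootstrap proportion BP(r) of replicates in
  which a tree attains the maximum is probit-transformed,
  z(r) = Φ⁻¹(1 − BP(r)), and fitted with z(r) = d√r + c/√r by weighted
  least squares with binomial delta-method weights; p_AU = 1 − Φ(d − c).
  BP values are clamped to [1/(2B), 1 − 1/(2B)] so the probit stays
  finite; if every BP clamps to the same side the tree dominates (or is
  dominated) and p is reported as 1 (or 0) with a degeneracy flag. Ties
  for the replicate maximum go to the first tree in input order; ties for
  best observed tree are flagged in the report.

## Substitution model and simulator

The simulator evolves sites along a newick tree under GTR+I+G:

* rate matrix Q with exchangeabilities r (r_GT ≡ 1) and stationary
  frequencies π, normalised so the mixture's expected substitution rate
  is 1 per unit branch length (branch lengths are expected substitutions
  per site);
* a proportion I of invariable sites (rate 0) and discrete-gamma rate
  heterogeneity (median method, 4 categories by default, category rates
  scaled by 1/(1 − I) so the I+G mixture has mean rate 1);
* root states drawn from π, children sampled from P(t·rate) computed by
  eigendecomposition of the reversible Q.

Defaults are the GTR+I+G fit of a fast-evolving green-algal SSU data set:
r = (1.4341, 2.6641, 1.2357, 1.6993, 5.2526, 1), π = (0.2338, 0.2439,
0.2871, 0.2351) (renormalised from the published 4-decimal values),
I = 0.6009, shape 0.6856; a TrN-style family-level fit is provided as a
second preset with the TrN constraint expressed as tied GTR
exchangeabilities. The study-shaped configuration
(`study_config`) emulates the data layout of such a survey: 1700 sites,
eight ingroup clades of three taxa plus four outgroup taxa on a
clade-structured tree (tip branches ~0.005–0.02, clade stems ~0.06–0.14),
a 130-column intron-style gap block carried by clades A–D, and planted
diagnostic columns and compensatory pairs in the post-block tail.

Planting operators write an inside state to all clade members; outside
taxa either have chance occurrences of that state rewritten, or (for
deterministic CBC ground truth) receive an explicit outside state.
Homoplasy injection writes the inside state into one random outside taxon
with a configurable probability, and the ledger marks the column broken —
the scanner must then drop it. Planted recovery is scored over planted
columns (recall, precision and CBC-class accuracy against the ledger);
clade-diagnostic columns that the substitution process itself produces on
clade stems are genuine NHS, not scanner errors, and the scanner's
exactness over whole alignments is fixed by the brute-force oracle
instead.

What the generator does not emulate: indels other than the single intron
block (real gap-rich regions are wider and ragged — but the masking step
removes them in the real workflow too), rate autocorrelation along the
sequence, secondary-structure-constrained compensatory evolution (planted
pairs are written post hoc, not co-evolved), base-composition
heterogeneity across lineages, and sequencing ambiguity codes. Passing
tests therefore demonstrate algorithmic correctness and calibration on
model data, not robustness to alignment error.

## Site-wise likelihoods

`sitewise_loglik` computes per-site log-likelihoods by Felsenstein
pruning with per-node rescaling, gaps/ambiguity codes as missing data
(partial likelihood 1 over compatible states), and the I+G mixture taken
per site via log-sum-exp. Zero site likelihoods (possible at zero branch
lengths with conflicting states) are reported as the sentinel −10⁹ rather
than −inf, so downstream matrix arithmetic stays finite. The total
log-likelihood is invariant to taxon order and, for reversible models, to
rerooting (asserted to 1e−8); the two-taxon JC case matches the closed
form (1/4)(1/4 + 3/4·e^{−4t/3}) to 1e−10.

## Intron screening

Presence of the group I intron is called positionally: a taxon is present
iff its non-gap fraction inside the block interval is at least
`min_occupancy` (default 0.5). The call is monotone in the threshold and
order-independent. A helper converts reference-sequence coordinates (for
example, the insertion position in a chosen reference taxon) to alignment
columns through the reference gap pattern. No motif or folding model is
used.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 1000 random alignments
(4–30 taxa × 50–500 columns) for the NHS oracle check; 100 simulator
seeds for planted recovery; 2000 replicates of 1645 sites for the
relative-rate null; 20 settings at B = 10⁴ for KH versus the analytic
tail; B = 4·10³ per scale for the AU checks; and 10⁵ sites for the JC
divergence and stationarity checks. These sizes put Monte-Carlo error
well below the assertion tolerances while keeping a full run of suite
plus script around a minute of CPU.

## Known limitations

* The genus-level census row is only meaningful when the alignment
  contains taxa outside the targeted clades; with full coverage it counts
  strictly conserved columns.
* NHS numbering is per-run; cross-run identity is by column, not ordinal.
* The AU implementation uses the probit WLS fit of the multiscale model,
  not the full iterative maximum-likelihood fit; on two-tree problems it
  agrees with KH to Monte-Carlo error, and degenerate BP curves are
  flagged rather than extrapolated.
* The relative-rate group summary compresses many pair tests into one
  symbol; always read it with the exported detail table.
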