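# Methods

## Model and assumptions

The package estimates deterministic production technologies
`Ψ ⊂ R₊^{m+s}`: every observed DMU `(x_i, y_i)` is feasible, and free
disposability holds (if `(x, y)` is feasible, so is any `(x′, y′)` with
`x′ ≥ x`, `y′ ≤ y`), which forces the frontier to be non-decreasing in
every input.  There is no stochastic noise term; all deviation below the
frontier is read as technical inefficiency.  Output-oriented efficiency
under variable returns to scale is
`φ(x_k, y_k) = max{φ : (x_k, φ·y_k) ∈ Ψ}`.

**FDH.**  `Ψ` is the free-disposal closure of the observations.  The score
reduces to dominance enumeration, `φ_k = max_{j: x_j ≤ x_k} min_r y_rj/y_rk`,
computed exactly with weak inequalities and no comparison tolerance:
inputs are finite-precision table values, and a tolerance would silently
change the envelope.  Peer ties break toward the lowest DMU index.

**EAT.**  A binary tree recursively partitions input space into half-open
boxes `[lo, hi)`.  A node with at least `numstop` observations is split at
the `(j, s)` minimizing `R(t_L) + R(t_R)` where
`R(t) = (1/N) Σ_{i∈t} ||y_i − y(t)||²`; candidate thresholds are the
observed values of `x_j` inside the node and the left child takes
`{x_j < s}`, so fitted frontiers step at observed input levels.  During
growth, a child's estimate is the componentwise maximum of its observed
outputs and of the estimates of already-terminal nodes whose support lower
corner is dominated by the child's lower corner; the fresh left leaf also
backs up the right one.  Ties among equal-error splits go to the lowest
variable index, then the smallest threshold, making growth deterministic.
Terminality: node size below `numstop`, depth equal to `max_depth` (edges
from the root; root depth 0), or no split producing two nonempty children.

*Monotone finalization.*  Corner-dominance backups alone cannot guarantee a
monotone leaf-constant predictor: two leaves can have Pareto-incomparable
lower corners (e.g. `(0, 3)` vs `(5, 0)`) while one still contains points
dominated by points of the other, so a high estimate may fail to propagate.
After growth (and again after pruning) the leaf estimates are therefore
finalized as the minimal monotone closure of the per-leaf observed maxima:
`fest(t) ≥ fest(t′)` is enforced to a fixpoint whenever
`lo(t′) < hi(t)` componentwise, which is exactly the condition that some
point of `t′` is dominated by some point of `t`.  The result is the
smallest leaf-constant envelope of the data that is globally
non-decreasing — the two contracts (monotonicity on arbitrary ordered
pairs, envelopment of every training observation) are property-tested.
Growth-time estimates are kept separately and drive split selection and
pruning, so the selection criterion follows the node-wise estimation rule
verbatim.

*Pruning.*  Standard weakest-link cost-complexity pruning: link strength
`g(t) = (R(t) − R(T_t)) / (|T_t| − 1)` on growth-time errors yields an
increasing complexity sequence; representative parameters (geometric means
of consecutive distinct values) are scored by k-fold cross-validation,
regrowing a tree on each training fold, pruning it at each candidate, and
summing held-out squared error.  The minimizing parameter is chosen with
ties resolved toward the larger parameter (smaller subtree); no 1-SE rule.
Fold assignment is seeded and logged in the pruned tree's metadata.

*Efficiency.*  The mixed 0/1 radial program over terminal nodes (one-hot
selection `λ`, feasibility `Σ λ_t a^t ≤ x_k`) collapses to leaf
enumeration: `φ_k = max_{t: a^t ≤ x_k} min_r d_r(a^t)/y_rk` with
`a^t = lo(t)` and `d(a^t)` the leaf's finalized estimate.  Root-side
unbounded coordinates have `a^t_j = 0`, so the origin leaf is feasible for
every DMU and the DMU's own leaf guarantees `φ_k ≥ 1`.  Equivalence with
exhaustive one-hot search is tested on trees with ≤ 8 leaves, and
`φ_EAT ≥ φ_FDH` holds because an FDH peer's leaf corner is dominated by the
scored DMU's inputs while its estimate envelopes the peer's outputs.

**RFEAT.**  `p` bootstrap samples (size n, with replacement) grow unpruned
trees, stopping at `n(t) ≤ n_min`, with a fresh random variable subset at
every split whose size follows one of five rules (floored, clamped to
`[1, m]`): Breiman `m/3`, DEA1 `n(t)/2 − s`, DEA2 `n(t)/3 − s`, DEA3
`n(t)/(2s)`, DEA4 `min{n(t)/s, n(t)/3 − s}`, the DEA rules evaluated at the
parent node's size.  The forest predictor is the plain average of tree
predictors — monotone as an average of monotone functions, but not an
envelope of the data, so `φ_RFEAT = min_r ŷ_r(x_k)/y_rk` may fall below 1.
OOB error is the squared error of the OOB-averaged prediction, summed over
outputs and averaged over observations that are out of bag at least once
(never-OOB observations are excluded and counted).  Permutation importance
%Inc permutes one input column, re-evaluates the *fitted* trees at the
permuted points through the same OOB averaging, and reports the percentage
increase in OOB error; a zero baseline error makes %Inc undefined and is
reported as such.  A single master seed derives the bootstrap draws and
per-tree variable-subset streams, so a seed reproduces a forest
bit-identically.

**Ranks and reports.**  Reciprocals `1/φ` are ranked by competition
ranking (ties share the minimum rank; the next distinct value skips) on
values rounded to 3 decimals, matching the granularity of printed score
tables; unrounded ranks are also emitted.  Rank correlations are Pearson
correlations of those competition ranks (the printed convention), with the
average-rank Spearman variant emitted alongside.  Score correlations use
`φ`.  Quartile groupings use the (n+1)-quantile convention with a value
equal to a cut assigned to the lower bin, so ties stay together; densities
of `1/φ` use a Gaussian kernel with Silverman's bandwidth on a shared grid,
and the "mass at 1" is the integral over `[0.999, 1.001]`.

## Ingestion rules

Inputs and grouping variables are arithmetic means over the analysis-window
years with available values (default window 2017–2021); a DMU is dropped
only when an input series is missing for the *whole* window, and the drop
is logged in provenance.  The output is taken at a designated year, and if
missing there, from the nearest available in-window year with ties broken
toward the later year ("closest available data" leaves the direction open;
the later year is closer in information content to the target).  Grouping
variables follow the same window-mean rule — a user supplying a single
stated year per grouping variable recovers single-year behaviour exactly.
Units are never converted and validation is numeric-only (nonnegative
inputs, strictly positive outputs), since typical panels mix PPP dollars
and percentages deliberately.

## Synthetic data

`gen_oecd_like` draws truncated-normal marginals matched to published
(mean, SD, min, max) moments of a 36-country OECD health table — per-capita
medical spending, public health expenditure share, per-capita GDP, upper-
secondary net enrollment, health spending as %GDP, life expectancy, plus
out-of-pocket spending and old-population ratio as grouping variables —
with a shared latent factor giving the wealth-linked indicators a mild
positive rank coupling (ρ = 0.5; the source table prints no correlations,
so this is a deliberately conservative choice).  It emulates marginal
location/spread and one plausible dependence direction only: it does not
reproduce the real indicators' joint distribution, so tests passing on it
demonstrate algorithmic correctness and qualitative behaviour (e.g. the
FDH > EAT > RFEAT discrimination ordering), not country-level conclusions.

`gen_known_frontier` samples inputs uniformly on a box (default `[1, 10]^m`
so that origin-cornered leaves stay non-trivial), evaluates a known
monotone frontier `f(x) = a + b·Π x_j^{α_j}` (defaults `a = 2`, `b = 1`,
`α_j = 0.4`), and applies one-sided half-normal inefficiency
`y = f(x)·exp(−|N(0, σ_u)|)` — the standard deterministic-frontier noise
model.  Defaults for the recovery experiments are `m = 2`, `n = 50`,
`σ_u = 0.1`, 50 replicates: large enough for stable majority statistics,
small enough that the full suite runs in about a minute.

## Numerical choices and degenerate inputs

* Split/prune tie tolerances are relative (`1e-12`), used only to stabilize
  argmin selection; dominance and rank comparisons are exact.
* Error normalization uses the full training size N at every node, so
  sibling errors add to comparable scales and `R(T)` is a per-sample
  quantity.
* A node whose observations are constant in all allowed inputs cannot
  split and becomes terminal; a constant-output node splits freely (zero
  error either way) under the deterministic tie-break.
* Degenerate moment specs (`SD → 0`) yield constant columns; degenerate
  score columns make correlations NaN with a warning, and all-equal
  reciprocal scores collapse the density report to a point mass.
* `mtry` rules that evaluate to ≤ 0 clamp to 1; a drawn subset with no
  valid split makes the node terminal (standard random-forest behaviour).

## Open design points resolved

* Thresholds are observed values with a strict-less left branch (printed
  reference trees show observed-scale thresholds); midpoint thresholds
  would shift frontiers off observed anchors.
* Hyperparameter tuning scores the *pruned* predictor by outer k-fold CV
  (`fold` from the combination), since pruning is part of the estimator
  being selected.
* Both published RFEAT configurations ({n_min = 7, p = 500, Breiman} and
  {n_min = 5, p = 1000, DEA1}) are runnable; neither is hard-coded as a
  default beyond `RFEATRegressor`'s constructor defaults (500, 7, Breiman).

## Known limitations

* Growth is exhaustive over observed thresholds (`O(m·n²)` per node): fine
  for benchmarking-scale data (tens to hundreds of DMUs), not tuned for
  large n.
* The monotone closure is computed over the final leaf partition; interior
  nodes keep growth-time estimates, so reported split gains are those of
  the growth criterion, not of the finalized predictor.
* Forest training is sequential by design — determinism under a single
  seed is part of the contract; there is no parallel-training mode.
* No input-oriented or hyperbolic orientations, no DEA convex hull, no
  slack-based or super-efficiency measures.
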