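# Methods

## The monitoring model

`milkfa` treats a dairy herd as a system moving between a small number of
latent states — feeding regimes and stress conditions — that leave
distinct signatures in the fatty-acid composition of the bulk-tank milk.
The pipeline estimates those states once, on a reference population, and
then monitors every herd by the probability of its current record
belonging to each state.

The stages, with their governing assumptions:

**Cleaning.** Records must have fat in [1.5, 9] g/dL, protein in
[1, 7] g/dL, no negative FA and no missing studied trait. Bounds apply on
the milk basis, before unit conversion, because conversion divides by fat
and therefore needs fat > 0 (cleaning guarantees ≥ 1.5). Each rejected
row gets exactly one reason — the first failing rule in the fixed order
fat-bound, protein-bound, negative-FA, missing — so rejection counts are
deterministic. Rows with *missing* fat or protein take the "missing"
reason: bound rules only judge observed values.

**Unit conversion.** FA concentrations are re-expressed as
`100 × FA / fat` (g/100 g fat). This decouples composition from yield and
fat content and is the basis on which all multivariate analysis runs.

**Reference PCA and GH.** Traits are centered and scaled to unit variance
(correlation-form PCA — the scaling matters because trait units span two
orders of magnitude) and the smallest set of components reaching the
`variance_threshold` (default 0.95) is retained. The threshold, not a
fixed component count, is the parameter: the retained count is a property
of the data. GH is the squared Mahalanobis distance of the retained
scores from the reference score mean divided by the component count;
µ̄ and S come from the reference population only and are frozen, so an
external population projected onto the same axes is scored on the
reference's geometry. On Gaussian reference data nPC·GH ~ χ²(nPC), hence
mean GH ≈ 1 and the GH > 5 tail is essentially empty — both are tested.

**Stratified subsampling.** Ward clustering stores O(n²) distances (the
implementation refuses more than 30,000 rows by default), so the
clustering subset keeps the entire GH ≥ 3 tail and draws
`per_stratum_n` records uniformly without replacement from each of
[0, 1), [1, 2), [2, 3). Intervals are half-open so the strata partition
the line; a stratum smaller than the draw size is taken whole and
reported as a shortfall rather than erroring, which keeps small runs
usable. The library default draw is 5,000 per stratum (the published
design); the pipeline config ships a 400-per-stratum desk-scale default.

**Ward clustering and k selection.** Linkage uses the Ward criterion via
the Lance–Williams recurrence on squared Euclidean distances with heights
on the distance scale (the ward.D2 convention; scipy's `ward`). Features
are standardized first, consistent with the classifier preprocessing.
Correctness is pinned by an exhaustive oracle that recomputes every
inter-cluster Ward cost from scratch at each step on all small instances.
k is chosen as the argmax over [k_min, k_max] (default [2, 15]) of the
relative height gap `(h[n−k] − h[n−k−1]) / h[n−k−1]`; the full gap table
is always returned because the rule is a codified surrogate for a visual
dendrogram judgment, and a human should be able to overrule it. Clusters
are renumbered 1..k by decreasing size (ties keep the original order) so
reports are stable across runs.

**Classification.** PLS-DA regresses the one-hot label matrix on
centered/scaled features, with the component count (≤ 30) maximizing
cross-validated accuracy; predicted indicator scores are clipped at zero
and renormalized into row-stochastic probabilities (all-non-positive rows
fall back to uniform). The random forest uses 500 Gini trees by default
with `max_features` tuned by CV over {√p, p/3, p/2}; its membership
probability is the proportion of trees voting for each cluster — the
quantity the alert layer consumes. Cross-validation is stratified by
class and seeded; unstratified folds can lose a rare cluster entirely.
Both pooled and per-fold metrics are reported: pooled accuracy is the
record-weighted mean of fold accuracies, which is why the two reporting
conventions can differ by a fraction of a percentage point. Hard labels
are the probability argmax with ties to the lowest cluster index.

**Dynamics.** Transitions are counted over consecutive within-herd record
pairs, pooled across herds (never across a herd boundary), and
row-normalized. Rows with no observed departures are reported as missing,
not invented as uniform. No gap exclusion is applied by default —
successive tank records are 1–3 days apart by construction — but
`max_gap_days` is available for sparse data. The stationary distribution
(left unit eigenvector) requires an irreducible chain; reducible input is
rejected with the component count.

**Interpretation and alerts.** Cluster summaries rank per-trait means
under an "is high favourable?" orientation. Orientation is expert
judgment, not a formula; the shipped defaults reflect the reference
population's reading (de novo/short-chain FA and the productivity
auxiliaries favourable high, mobilisation markers such as C18:1 cis-9 and
blood free FA favourable low) and are fully overridable. The default flag
map sends cluster 3 to red, clusters 2/5/6 to orange, and 1/4/7 to green
under the Walloon numbering; because fitted cluster numbers are
size-ordered per run, the map must be re-pointed after inspecting the
summary. Threshold mode escalates a record whenever a mapped cluster's
probability exceeds the threshold even if it is not the argmax — an
early-warning reading of the probability series. The default episode
filter raises an alert on ≥ 2 consecutive non-green records, since a
single aberrant tank sample is noise at a 1–3-day rhythm.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not dairy biochemistry. Herds follow a first-order Markov chain over 7
states whose transition matrix, per-state trait means, and trait
dispersions come from the Walloon reference parameter set
(`milkfa.reference`). Within a state, records are conditionally
independent Gaussian draws with covariance `(f·SD)²` on the diagonal
(`f` = `within_state_sd_fraction`, default 0.5, optional user-supplied
trait correlation): the published tables give no within-cluster
covariances, and the fraction is chosen so between-state spread dominates
within-state spread, the regime in which 7 states are recoverable at all.
Printed transition rows sum to 99.99–100.01 from rounding and are
renormalized. The initial state distribution defaults to uniform.
FA draws are truncated at zero (true negatives are artifacts, injected
separately); sampling gaps are uniform on {1, 2, 3} days. Spectra are a
fixed seeded linear image of the FA traits plus iid noise — invertible in
expectation, deliberately not physical. Artifact injection flips rows out
of the cleaning bounds, negates one FA, or blanks one trait, each with
its own per-row rate, and returns a perturbation log that the cleaning
tests reconcile against.

What passing tests therefore show: the estimators recover the generating
truth (transition probabilities, state means, k, labels) under the
assumed structure. What they do not show: performance under correlated
within-state noise, autocorrelated residuals within herds, seasonal
drivers, or real FT-MIR prediction error — on real data the states are
less separable (the identity within-state correlation makes synthetic
classification nearly perfect, where real-data accuracy sits near 90%).

## Numerical choices

- Transition rows are validated to sum to 1 within 1e-9; probability rows
  from classifiers likewise.
- Chain simulation uses per-row inverse-CDF sampling (one uniform per
  step) for exact reproducibility under a seed.
- The nearest-station rule breaks distance ties toward the lowest
  station id, making assignment invariant to station row order.
- Ward tie-breaks follow scipy's nearest-neighbour-chain order; on
  continuous data ties have measure zero, and the exhaustive-oracle tests
  use random continuous instances.
- `ReferenceProjection` serializes to JSON with full-precision floats and
  round-trips exactly; the score covariance inverse is recomputed on load.
- Degenerate inputs: constant traits are rejected before PCA; a
  degenerate (flat) dendrogram gap profile falls back to `k_min` with a
  warning; single-record clusters report a missing SD; empty transition
  rows stay missing.

## Problem sizes

Tests and the acceptance script run on scaled-down instances chosen to
keep the statistical claims sharp: ~3,600-record populations for
estimator checks, ~4,000-record populations with a 400-per-stratum
subsample for the k-recovery replicates, 20,000–50,000 Gaussian rows for
the GH distributional identities, and ~33,000 observed transitions
(>10,000 departing state 1) for the transition-recovery benchmark, where
the binomial standard error of the recovered entry is ~0.4 pp against a
±2 pp tolerance.

## Known limitations

- Conditional independence within herds: no residual autocorrelation
  beyond the state label.
- Point-based nearest-station assignment stands in for polygon-overlap
  municipality linkage; no CRS handling.
- Same-day THI only; no lagged or rolling heat-stress exposure.
- PLS-DA probabilities are clipped indicator scores, not calibrated
  probabilities.
- The flag map and trait orientation are conventions to be reviewed per
  deployment, not estimated quantities.
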