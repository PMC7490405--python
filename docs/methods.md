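# Methods

This note documents the modelling assumptions, defaults and numerical
choices behind `adhertype`, and what the synthetic cohorts do and do not
establish about behaviour on real monitoring data.

## Dose model and ingestion

Each patient on a twice-daily regimen has two *potential doses* per
calendar day. A dose is one or more actuations within a half-open 12-hour
window: [00:00, 12:00) is the AM dose, [12:00, 24:00) the PM dose (12:00
exactly is PM; the half-open convention makes the boundary unambiguous).
Multiple actuations in one window collapse to one dose, so doses per day
are in {0, 1, 2} regardless of puff counts.

Device-malfunction periods (battery failure recorded in the device log) are
masked: the affected days are set unobserved, any actuation recorded inside
a declared block is treated as spurious and discarded, and the "days with
device" denominator counts only observed days. Follow-up windows come from
cohort metadata, not from the first/last event, so a dose-free tail counts
as non-adherence rather than vanishing from the denominator. Events outside
a patient's follow-up window are discarded with a warning; a patient with
zero observed days is excluded with a warning. Person-days are conserved:
observed + masked = the raw calendar, for every run.

## Adherence measures

With n observed days and d0/d1/d2 days with 0/1/2 doses:
A = 100(d1 + 2d2)/(2n), B = 100·d0/n, C = 100·d2/n,
D = 100·(# intermissions)/n, E = 100·(intermission days)/n.

A treatment intermission is a maximal run of at least `min_intermission_days`
(default 5) consecutive zero-dose days. Runs are computed within contiguous
observed segments: a masked day terminates a run without counting toward
it, and the two fragments around a masked gap are not joined — masking must
never fabricate missed doses. A run still open at the end of follow-up is
*censored*; censored intermissions are counted in D and E with their
truncated duration by default (`include_censored=False` drops them), since
the measures are summaries over the observation window and dropping an
ongoing gap would understate non-persistence. Time to first intermission
and first-intermission duration are computed as descriptive outputs only;
they never enter the clustering.

Invariants enforced by tests: A = (100 − B + C)/2 exactly; E ≥ 5·D; the
detector agrees with an exhaustive day-range oracle on random grids.

## Scaling, PCA and component retention

Three pre-processing regimes are compared: zero-centering only,
unit-variance standardisation and min–max scaling to [0, 1]. Unit-variance
scaling divides the centred columns by the population standard deviation;
a `variance_divisor="variance"` option divides by the variance instead,
because "scaling to unit variance" is occasionally implemented that way and
the two are not equivalent. Constant columns are an error under the two
spread-dependent regimes (named in the message).

PCA uses the full SVD. Component signs are arbitrary, so each component is
flipped to make the first variable (measure A) load non-negatively. Two
loading representations are kept: the orthonormal eigenvector basis
(`loadings`) and the variable–component correlation coefficients
(`correlations`), the ±1-bounded quantities conventionally tabulated.
The retained component count is the smallest m whose cumulative explained
variance reaches the threshold (default 0.95, compared with a 1e−12 slack
against floating-point shortfall). Clustering consumes the scores of the
retained components only, since component selection precedes clustering in
the protocol.

## Clustering, k selection and stability

k-means runs with 25 initiations (scikit-learn's k-means++ seeding; the
substance of the protocol is the 25 restarts, and the better-seeded
optimiser only tightens the within-group sum of squares) for k = 1..15,
deterministically seeded. The WSS curve is non-increasing in k up to
optimizer tolerance; for k beyond the number of distinct points the WSS is
exactly that of the distinct-point solution (0), and the curve clamps k
there rather than erroring.

Visual scree inspection is automated as the maximal-chord-distance rule:
min–max normalise both axes, join the first and last curve points by a
chord, and pick the interior point at maximal perpendicular distance (ties
toward smaller k; a flat curve returns k = 1 with a warning, an exactly
linear curve warns and returns the smallest interior k). A config override
(`k_override`) preserves analyst judgement.

Stability: 1,000 bootstrap replicates by default. Each replicate resamples
patients with replacement and re-clusters the resample with the same k and
25 initiations (the protocol does not say whether the restarts applied per
replicate; applying them is the configurable default). Each original
cluster is restricted to the unique patients present in the resample
(membership, not multiplicity, is what the Jaccard coefficient compares)
and matched to the resample cluster with the highest Jaccard similarity;
a best match below 0.5 is a dissolution. Per-cluster mean Jaccard and
dissolution rates are reported; the scaling regime with the highest mean of
per-cluster mean Jaccards wins (ties: lower mean dissolution, then method
order center_only, unit_variance, min_max). Clusters are finally renumbered
1..k by ascending median of measure A (ties: larger cluster first), so
cluster 1 is always the poorest-adherence group.

## Surrogate tree

One CART per measure, univariate by design: the point is a single-number
bedside approximation of the typology, not a better classifier. Constraints:
≥ 20 patients at a node to consider a split, ≥ 6 per leaf, at most two
split levels ("height 2" read as two levels of splits, ≤ 4 leaves, matching
the shallow published tree; configurable). Splits minimise Gini impurity
with thresholds at midpoints between adjacent observed values — with one
predictor the greedy search is exhaustive, which the tests exploit as an
oracle. The pruning level is the candidate from the nested cost-complexity
sequence minimising 10-fold cross-validated misclassification (ties toward
the simpler tree). CV folds are label-stratified and seeded — stratification
avoids folds that lose a class entirely in small cohorts and does not
change the estimand. Fewer than 20 patients yields a root-only majority
tree with a warning.

Partitioning is uniform random and unstratified: validation and test sizes
are nearest-integer allocations of their fractions and the remainder goes
to training, so 211 patients under 0.70/0.15/0.15 give 147/32/32. The
protocol's descriptions of the split disagree internally (a three-way
70/15/15 protocol versus a 70/30 train/test description); the three-way
protocol is primary because it matches the published 32-patient test set,
and a 70/30 mode is available via `split_fractions=(0.7, 0, 0.3)` (measure
selection then falls back to training accuracy, with a warning). The best
measure maximises validation accuracy (ties toward A before B … E); the
final confusion matrix (rows = tree estimate, columns = cluster label) and
accuracy = trace/total are computed on the untouched test partition.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes: 211
patients by default, follow-up uniform on 155–210 days, twice-daily dosing,
actuation clock times drawn inside 07:00–10:00 with probability 0.96 (AM)
and 19:00–22:00 with probability 0.93 (PM) and uniformly over the half-day
otherwise, and per-patient battery-failure blocks (probability 0.26 of one
block, log-normal length with median 22 days clipped to 2–122).

Behaviour is a three-archetype mixture (weights 0.30/0.40/0.30):

| archetype | dose prob. | intermission hazard /day | mean duration (d) |
|---|---|---|---|
| poor | 0.25 | 0.054 | 10 |
| moderate | 0.62 | 0.012 | 8 |
| good | 0.92 | 0.0008 | 7 |

During an intermission all dose probabilities are zero; durations are
5 + geometric extra days, so every generated intermission meets the 5-day
persistence definition (chance runs of zero-dose days add further, shorter
or longer, gaps — intentionally). These parameters were fixed once so the
archetype medians of measure A bracket roughly 16% / 55% / 91%, the
poor-archetype intermission rate sits near 4 per 100 days, and the
archetype-wise interquartile ranges of A do not overlap at cohort sizes of
150+. An optional two-arm mode reweights the mixture per arm
(0.55/0.35/0.10 vs 0.05/0.25/0.70) to emulate a low-adherence control arm
(mean A ≈ 36%) against a high-adherence intervention arm (≈ 80%); it is off
by default. Timestamps are serialized in ISO 8601 at minute precision,
which is sufficient for 12-hour window assignment. A fixed seed gives
byte-identical CSVs; all pipeline randomness derives from one master seed
through SHA-256-hashed named substreams (generator, clustering, bootstrap,
partitioning, CV), so stages re-run in isolation reproduce their part of a
full run.

What the generator does **not** emulate: within-person behaviour change
over time (archetype parameters are time-constant), dose dumping or
technique errors, seasonal or weekday structure, and informative
missingness (battery blocks are placed uniformly at random). Passing the
simulation-backed tests therefore shows that the pipeline recovers a known
typology under its own assumptions — clean archetype separation, stationary
behaviour — not that three clusters exist in any particular clinical
cohort, nor that real clusters would be as stable as the synthetic ones.

## Problem sizes used in testing

The parameter-recovery and surrogate-selection properties run the full
chain on 20 seeded cohorts of 200 patients; stability calibration uses 200
bootstrap replicates on simulated well-separated groups (three Gaussian
blobs at ≥ 10× the within-group spread) and on structureless uniform data.
The structureless check uses 5-dimensional uniform points: in one or two
dimensions k-means partitions of uniform data are often geometrically
stable and dissolution is erratic across draws, whereas in five dimensions
elevated dissolution is a robust property of the configuration rather than
of a particular seed. The full pipeline default remains 1,000 bootstrap
replicates.

## Known limitations

- The elbow rule is a heuristic; curves without a single clear knee can
  select degenerate k (hence the override and the emitted warnings).
- Loading tables from different scaling regimes are not directly
  comparable; only the correlation representation is scale-invariant.
- Bootstrap Jaccard stability is assessed at the selected k only; it does
  not compare k choices.
- With five measures and shallow trees the surrogate cannot represent
  non-monotone cluster boundaries in a single measure.
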