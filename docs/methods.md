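# Methods

## The monitoring problem

Communities in rare, physically variable habitats cannot be assessed with
before/after-control/impact designs: there is no comparable control site, and
inherent variability makes "significant change" the norm rather than the
exception. The workflow implemented here therefore has two layers. The first
is conventional: quantify spatial and temporal structure (PERMANOVA,
PERMDISP, SIMPROF clustering) on Bray–Curtis dissimilarities of
fourth-root-transformed abundances. The second reframes the question:
multivariate control charts characterize *background* variability and flag
only observations that deviate more than the background allows.

## Resemblance and transformation

Abundances are fourth-root transformed before any resemblance computation.
The transform compresses numerical dominance (taxa in these systems span
about three orders of magnitude), so the whole community rather than one or
two dominants drives the analysis. Bray–Curtis dissimilarity
`d_ij = Σ_k |y_ik − y_jk| / Σ_k (y_ik + y_jk)` is stored on the 0–1 scale.
Two all-zero samples have an undefined ratio; they are treated as identical
(`d = 0`) with a warning, so degenerate simulated inputs do not abort a
pipeline.

## Geometry of a semimetric space

All tests operate on the Gower-centered matrix `G = −½ J D² J`. Bray–Curtis
is semimetric, so `G` has negative eigenvalues; principal coordinates are
kept as separate real and imaginary axis sets, and every squared distance is
the real-axis part minus the imaginary-axis part (the standard distance-based
MANOVA treatment; no Lingoes/Cailliez correction). Centroid–centroid squared
distances are computed directly from `D²` via

```
‖c_A − c_B‖² = S(A,B)/(n_A n_B) − S(A,A)/(2 n_A²) − S(B,B)/(2 n_B²)
```

with `S(X,Y)` the full double sum of squared dissimilarities; per-sample
distances to a group centroid (PERMDISP) use the signed embedding. Negative
squared results (possible for semimetric input) are clipped to zero; the raw
values are recorded in a diagnostics stream so their frequency and magnitude
are inspectable. Eigenvalues below `1e-9 · max|λ|` are treated as noise.

## PERMANOVA

One-way design: `SS_total = tr(G)`, among-group SS from the group-membership
projection; pseudo-F is the ratio of mean squares. P-values use unrestricted
permutation of raw data (whole-sample relabelings). Two-way crossed mixed
model (one fixed factor, e.g. year; one random, e.g. plot): Type III sums of
squares from differences of hat-matrix projections (sum-to-zero effects
coding; for nested projections `tr((H_f−H_r) G (H_f−H_r)) = tr((H_f−H_r) G)`),
and p-values by Freedman–Lane permutation of residuals under the reduced
model: for each term, `G` is residualized by the reduced-model projector,
rows/columns are co-permuted, and the term's statistic recomputed.

Pseudo-F denominators follow the restricted mixed-model expected mean
squares by default — fixed main effect over the interaction MS, random main
effect and interaction over the residual MS; `ems="unrestricted"` tests both
main effects over the interaction MS. Components of variation are
method-of-moments estimates from those same EMS (balanced designs only;
negative estimates report as zero with the raw value retained).

Conventions, fixed everywhere:

* p = `(1 + #{stat_perm ≥ stat_obs}) / (1 + B)`; ties count via `≥` with a
  relative tolerance of 1e-9.
* When the permutation space is no larger than the requested B, it is
  enumerated exhaustively (distinct label arrangements for the one-way
  design, all N! row permutations for residual permutation) and the exact
  proportion reported.
* `SS_total = 0` (all samples identical): pseudo-F := 0, p := 1.
* Permuted residualized traces can be negative or — for some structurally
  degenerate permutations of very small designs — exactly zero. The permuted
  statistic keeps its sign; ratios with `|denominator| ≤ 1e-10·SS_total`
  resolve to signed infinity (or 0 when the numerator also vanishes). This
  rule is part of the statistic's definition so that exhaustive enumeration
  is reproducible across implementations.
* One master seed fans out to named, label-keyed sub-streams, so toggling one
  analysis never shifts another's randomness.

Pairwise comparisons re-run the design on the two-level subset and report
`t = √pseudo-F`. A level whose samples all fall in one cell of the random
factor cannot be tested (the design is confounded) and raises an error —
mirroring the "n/a" entries real monitoring tables contain when a year is
missing at some plots.

## PERMDISP

Distances of samples to their own group centroid (signed convention) are
compared across groups with a classical one-way ANOVA F; significance by
permuting group labels and recomputing the distances. Groups need at least
two members. The observed distances are exposed for inspection.

## SIMPROF clustering

UPGMA is implemented directly (inter-cluster distance = arithmetic mean of
cross-pair dissimilarities) with a deterministic tie-break — among equally
close pairs, the pair whose lexicographically smallest member labels sort
first — so dendrograms are reproducible; scipy's average-linkage heights
serve as an independent check in the tests. The similarity-profile test
compares the sorted vector of within-set pairwise dissimilarities with its
mean under independent within-taxon permutation (which preserves each
taxon's abundance distribution but destroys associations):
`π = Σ_k |s_(k) − s̄_(k)|`, p from further permutations against the same mean
profile (defaults: 1000 permutations for the mean, 999 for the test).
Profiles are computed on the same transformed matrix the dissimilarities came
from, so profile and dendrogram are commensurable. The random stream is
consumed in sorted-label order, making results invariant to row/column order.
Cluster output is the top-down traversal of the dendrogram that stops at
nodes without significant internal structure; subsets of fewer than three
samples are untestable and terminal.

## Multivariate control charts

A (plot, time) observation is the set of its replicate samples; its community
is their centroid. Two deviation series per plot:

* **baseline** — `d_t` = distance from the time-t centroid to the centroid of
  all samples in the plot's first `m` times (default m = 2); sensitive to
  sustained, gradual ("press") change. Baseline times are charted but not
  flagged by default.
* **sequential (t−1)** — `d_t` = distance to the centroid of all samples at
  times 1…t−1; the reference moves with the data, so one-off ("pulse")
  change stands out. The first charted point (reference = a single time) is
  annotated "unstable": the moving centroid needs a few years to settle, and
  early exceedances are usually artifacts.

Deviations are reported on the Bray–Curtis root scale (square root of the
squared centroid distance), matching the 0–1 axis of the resemblance measure.

Control limits: for each of B bootstrap iterations (default 10000), each
plot's time-point observations are resampled with replacement (an
observation's replicate set travels together), assigned to time positions in
draw order, and all deviations recomputed; deviations are pooled across all
plots of all sites and the 50th/95th percentiles recorded — pooled over time
for the baseline chart (its bootstrap percentile distribution is
time-invariant), per time index for the sequential chart. The limit is the
mean of each percentile over the B iterations. Percentiles use
linear-interpolation (type-7) empirical quantiles. Internally the bootstrap
runs on precomputed block sums of squared dissimilarities between
(plot, time) cells, which is algebraically identical to recomputing the
centroid identity on unions of replicate sets (asserted in the tests).

A deviation above the 95th-percentile limit is flagged out of control.
Flags are alarm signals for investigation; the charts attribute no cause.

**Known property of the limit estimator.** The per-iteration percentile is
taken over a pool whose size is the number of plot series (times, for the
baseline chart, the number of charted times). With a small pool — e.g. the
nine series of a three-site, three-plot network — the per-draw 95th
percentile of nine values estimates roughly the 87th percentile of the
underlying deviation distribution, so the realized per-series false-alarm
rate of the nominal 95% limit is about 11–12% rather than 5% (measured on
stationary synthetic networks in the test suite). This is structural to the
"mean of bootstrapped percentiles" construction at small network size, not
an implementation artifact; users monitoring few series should read the 95th
limit as an operational alarm threshold rather than an exact tail
probability. Pooling more series (≈20+) brings the realized rate near
nominal.

Sites sampled without distinct plots are handled by randomly partitioning
each time's replicates into k pseudo-plots (sizes within one of each other,
label-keyed and seed-deterministic), so a comparable chart can be built.

## Synthetic communities

The generator emulates replicated benthic monitoring data. Per-taxon base
expectations are log-spaced so the most and least abundant taxa differ by
exactly `10^span` (span 3 by default, top expectation 200 individuals per
standard sample area). Plot, year and plot×year effects are drawn once per
(site, level, taxon) as normals on the log scale — so effects are
multiplicative on abundance and shared by replicates — with default standard
deviations 0.5 / 0.3 / 0.3: values that put the realized components of
variation near the 10–15% per factor seen in long-running lagoon series,
with most variance residual. Counts are gamma-Poisson (negative binomial)
with shared shape k = 2 (variance `μ + μ²/2`), a typical overdispersion for
patchy sediment fauna; `overdispersion=None` gives the Poisson limit. The
default design template is one site × 3 plots × 5 years × 4 replicates × 30
taxa.

Disturbances modify expectations before counts are drawn: a pulse multiplies
a seeded taxon subset by a factor at one time; a press compounds a per-step
log trend from a start time. Both take an affected-taxon fraction (default
one half): a change applied uniformly to *all* taxa cancels exactly out of
Bray–Curtis after a power transform (numerator and denominator scale
together), so a partial footprint is what makes a disturbance visible to the
resemblance measure — as real disturbances are. The pulse fixture used in
the detection tests (multiplier 25, half the taxa) was set so the
final-year community shift is about three times the stationary inter-annual
shift. Ground truth (expected abundances, effect draws, disturbance
incidence) is returned alongside every matrix.

What the generator does not emulate: environmental drivers (salinity or
temperature series), taxon–taxon interactions, temporal autocorrelation
beyond shared year effects, and zero-inflation beyond what the negative
binomial produces. Passing tests therefore demonstrate statistical
correctness and power under a realistic abundance structure, not performance
on any particular real lagoon.

## Problem sizes and tolerances in the test suite

Euclidean-limit and enumeration oracles run on designs of up to ~27 samples
(agreement to 1e-10; ratios compared at 1e-10 relative where F is large,
since a ratio's absolute error scales with its magnitude). Calibration
checks use 1000 simulations × 199 permutations per test; chart
power/specificity 200 simulations with B = 400 bootstrap; variance-component
recovery 500 simulations. The full design-template workflow runs with 9999
permutations and B = 10000, as a monitoring program would.
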