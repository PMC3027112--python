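# Methods

## Data model

A dataset is a collection of log2 expression profiles indexed by (probe,
treatment, replicate). Each profile is a short list of (time, value) pairs
with strictly increasing times; replicates of the same treatment may have
different time grids and lengths, and individual measurements may be
missing. The design file assigns each array a treatment, a replicate number
(an opaque label — it need not be consecutive) and a time; a paired design
requires identical replicate-number sets across treatments, so that
replicate r in one treatment matches replicate r in the other. All analysis
assumes values are log2; the loader can apply the transform and refuses
non-positive values.

Parsing details the formats leave open were fixed as follows: missing cells
are empty fields or `NA` (case-insensitive); decimals may use scientific
notation; LF and CRLF both accepted; trailing blank lines ignored;
treatment names are case-sensitive opaque strings. The optional gene-symbol
column is detected from content (the second column is a symbol column iff
any of its entries fails numeric-or-missing parsing): with the number of
arrays unknown a priori, the header's field count alone cannot
disambiguate. A probe/replicate combination whose cells are all missing is
dropped with a warning — no downstream stage can use an empty profile.

## Curve evaluation and features

All features are computed on a user-chosen evaluation grid. Values off the
measured times are obtained by linear interpolation between the bracketing
measurements; measured times return the measured value exactly, and
extrapolation beyond the observed range is refused rather than guessed. A
warning (not an error) is emitted when more than 10% of a requested grid is
interpolated, since interpolation assumes local linearity the data cannot
confirm; the threshold is a guideline, not a hard rule.

- signed AUC: trapezoidal integral over the window, window endpoints
  interpolated; additive over adjacent windows and antisymmetric under
  negation of the curve by construction.
- slope: difference quotient between two (possibly interpolated) times.
  Note the quotient is *symmetric* under exchanging the two times — both
  numerator and denominator flip sign.
- extrema and their times: max/min of the grid-evaluated curve; ties break
  to the earliest grid time so results are deterministic. Extrema are
  deliberately computed on the common grid rather than raw per-replicate
  times so that all probes live in one comparable feature space.
- steepest positive/negative slopes: max and min consecutive-segment slope
  on the grid-evaluated curve. The "negative" slot holds the minimum slope,
  which is positive for a monotone increasing curve.
- raw expression: the grid values themselves, one feature column per time.
- single time point: the value at one chosen time. When requested for
  clustering without an explicit time, the last grid time is used.

Replicate summaries (mean or median) are taken per grid time over the
replicates whose observed range covers that time; a grid time covered by no
replicate is an error naming the time. For paired designs a relative
profile is the pointwise log2 difference of two treatments for one matched
replicate (a log ratio on the raw scale); paired-difference feature
matrices summarize these per-replicate differences across replicates.

## Significance screen

For each probe and each of the two treatments, the chosen feature (signed
AUC, slope, or time-point value) is computed once per replicate whose range
covers the needed times; uncovered replicates are skipped with a warning.
The two groups of per-replicate values are compared with Welch's unequal-
variance t-test (pooled-variance was deliberately not used; with unequal
replicate counts homoscedasticity is not guaranteed), Mann–Whitney U,
paired t or Wilcoxon signed-rank (paired designs only, matched by replicate
label, zero differences dropped), or a permutation t-test. Degenerate
inputs follow explicit conventions: zero variance everywhere with equal
means gives (statistic 0, p = 1); zero variance with unequal means gives
(±inf, p = 0); both are flagged.

The permutation test uses the Welch t (unpaired) or paired t statistic and
enumerates the complete null set — group relabelings C(n_a+n_b, n_a), or
2^n sign flips — whenever it has at most 20,000 arrangements, giving an
exact, seed-independent p as the two-sided tail fraction. Larger problems
fall back to seeded sampling with add-one smoothing,
p = (exceedances + 1)/(n_perm + 1) (default n_perm = 10,000), so p is never
0 and never below 1/(n_perm + 1).

Fewer than 3 replicates per group triggers a warning (power is poor below
that); groups that fall under 2 usable values are skipped with a reason
rather than tested.

### Outlier screens

Two families can run per group before testing.

The **mean–median screen** computes D = |mean − median| / (σ̂/√n) with σ̂
either the sample SD or the scaled MAD (1.4826·MAD); while D exceeds a
z-threshold (default 1.96) the value farthest from the median is flagged
and removed, stopping before the group drops below 3. σ̂ = 0 defines D = 0.
The two variants behave very differently and this is documented behaviour,
not a bug: a single gross outlier inflates the sample SD roughly as fast as
it moves the mean, so D for the SD variant tends to 1 as the outlier grows
and that variant only triggers on substantially skewed larger samples; the
MAD variant's robust scale makes it sensitive to exactly the single-gross-
outlier case.

**Dixon's extreme-value (Q) test** applies to 3 ≤ n ≤ 25 and can flag one
value in each tail per pass. The gap-ratio family follows standard
practice by sample size (r10 for 3–7, r11 for 8–10, r21 for 11–13, r22 for
14–25), compared against two-tailed critical values at α ∈ {0.01, 0.05,
0.10}. The embedded table uses the classic recomputed r10 values for
n ≤ 7; the remaining entries were calibrated to three decimals by
simulating two million normal null samples per n (the simulated quantiles
reproduce the published 5% and 10% columns to ≤ 0.008 where both exist).

By default a probe with any flagged replicate is excluded from the
significance table entirely and listed in the outlier report
(`outlier_action="remove-gene"`); `"remove-value"` instead drops only the
flagged replicates and tests the remainder. Both are exposed because the
exclusion convention is a policy choice, not a statistical necessity.

## Multiple-test correction and m0 estimation

Bonferroni is min(1, m·p). Benjamini–Hochberg is the classic step-up
q_(i) = min_{j≥i} m·p_(j)/j mapped back to input order. The adjusted FDR
replaces m by an estimate of m0, the number of true nulls — a step-up with
multiplier m0 — so its q-values are pointwise ≤ plain BH whenever m0 ≤ m.

**P-value-plot estimator.** The Schweder–Spjøtvoll plot graphs N_p, the
count of p-values strictly greater than p, against 1−p; under a full null
it is linear with slope m0. The `pvalue_plot` diagnostic returns the exact
step points at each distinct observed p. The *estimator*, however,
evaluates N_p on a fixed 101-point grid spanning all of [0, 1]: the null
region lives at large p whether or not any p-value was observed there, and
with every p tiny the grid-evaluated plot is flat at 0 over almost the
whole range, correctly driving the slope (and m0) to zero, whereas a fit
restricted to observed distinct p-values would degenerate. The fit region
starts as the quarter of grid points with the largest p and grows
point-by-point toward small p while the least-squares R² stays within a
tolerance (default 0.005, exposed as a flag) of the best R² seen; the
final slope, clamped to [0, m], is m0. m0 is reported rounded but
downstream rates use the unrounded value to avoid quantization at small m.

**CDF-area estimator.** The area under the empirical CDF of the p-values
on [0, 1] equals 1 − mean(p); a full null gives 1/2, so pi0 is estimated
as (1/2)/area, clamped to [0, 1]. The estimator is implemented exactly as
defined, which gives it a known floor: all-alternative data drive the area
toward 1 and the estimate toward 1/2, never lower. This bias is inherent
to the definition and documented rather than patched; the p-value-plot
estimator is the one validated for mixtures.

On simulated mixtures (m = 1000, alternatives Beta(0.05, 1), 200
replicates) the p-value-plot estimator's mean pi0 is within 0.1 of truth
at pi0 = 0.8 and both estimators average ≥ 0.95 at pi0 = 1; the m0-
adjusted BH at q ≤ 0.05 keeps empirical FDR near 0.05 on the pi0 = 0.8
mixture. These are the simulation conditions the test suite and
acceptance script run.

**Operating tables.** For each significance level α (default grid: 100
log-spaced points in [1e-4, 0.1]): S(α) observed p ≤ α, expected false
positives F = m0·α, sensitivity = clamp(S−F, 0, m−m0)/(m−m0) (undefined
when m0 = m), specificity = 1−α, FDR = min(1, F/max(S, 1)). ROC plot data
pairs (1−specificity, sensitivity); CDF and p-value plots are emitted as
(x, y) series ordered by x.

## Clustering

Because features mix units (times, log2 levels, slopes), columns are
standardized to mean 0 / SD 1 before clustering by default (zero-variance
columns are dropped with a warning); raw-distance clustering remains
available by standardizing upstream or not at all. Distances are Euclidean
or Manhattan.

**k-means** is Lloyd's algorithm with k-means++ seeding and 10 restarts,
keeping the best within-cluster objective (sum of squared distances under
Euclidean, plain distances under Manhattan); an emptied cluster is
reseeded with the point farthest from its centroid. Under Manhattan the
centroid update remains the arithmetic mean — the metric affects only
assignment and evaluation; a k-medians variant is a known, documented
limitation. Deterministic for a given seed.

**PAM** builds medoids greedily (first the point minimizing total
distance, then the point with the largest coverage gain) and then applies
best-improving medoid/non-medoid swaps until none improves. The swap
neighborhood has genuine local optima even on six-point instances, so the
swap phase is additionally restarted from seeded random medoid sets
(n_init − 1 of them) and the best final objective wins, with ties broken
toward the lexicographically smallest medoid set; on small instances
(n ≤ 10, k ≤ 3) this matches exhaustive search over all medoid subsets in
the test suite. Deterministic given the seed.

Silhouettes follow the standard definition with the singleton convention
s(i) = 0; each probe also reports its nearest neighboring cluster (the
argmin of b(i)). Homogeneity is the mean distance of probes to their
cluster representative (centroid for k-means, medoid for PAM); separation
is the size-weighted mean pairwise distance between representatives. Both
are representative-based reconstructions — an all-pairs variant would
differ by constants. The number of clusters is chosen by the highest
average silhouette over a user-supplied k range, ties to the smallest k.

## Synthetic data generator

The generator emulates the target regime: two treatments, a few replicates
each, a short base time grid (default 0, 2, 8, 24 h) optionally jittered
per replicate (uniform, bounded below half the smallest gap so order is
preserved), i.i.d. N(0, σ) noise on the log2 scale (default σ = 0.3, a
typical between-replicate spread for well-normalized arrays), per-gene
baselines N(7, 1), optional missing cells, and optional pairing (paired
replicates share their jittered grid). Null genes share mean profiles
across treatments; alternative genes add an effect profile to the second
treatment — constant shift, linear ramp, or mid-course Gaussian peak —
with default amplitude 1.0 log2 units. Output is emitted as input-format
text and re-parsed, so the generator also exercises the parsers.

What it does *not* emulate: gene–gene correlation, intensity-dependent
variance, platform artifacts (background, dye bias) and count noise.
Passing tests therefore demonstrate correctness of the algorithms under
the stated sampling model, not robustness to real-array pathologies.

A direct p-value generator (uniform nulls plus Beta(a, b) alternatives,
default Beta(0.05, 1)) drives the multiple-testing simulations without the
expense of full dataset screens.

## Numerical and policy choices

- Exact permutation enumeration bound: 20,000 arrangements; beyond it,
  seeded sampling with add-one smoothing.
- Welch's t at 4 replicates per arm is mildly conservative (Monte-Carlo
  type-I error ≈ 0.042 at α = 0.05); null-calibration checks should expect
  rejection rates at or slightly below the nominal level.
- Ties everywhere break toward the lowest index / earliest time / smallest
  k, so all outputs are deterministic given a seed.
- Simulation sizes in the test suite (500-gene null screens, 200-replicate
  p-value simulations at m = 1000, 20-seed cluster recoveries, 50-instance
  PAM/brute-force comparisons) are the package's chosen validation
  conditions; the acceptance script re-runs the same computations from a
  user seed.
- Result TSVs render floats at 6 significant digits; the simulation file
  writers use full repr precision so round-trips are lossless.
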