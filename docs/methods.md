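# Methods

## The statistics

**Cohen's d.** `d = (mean(x) - mean(y)) / sigma`. The default
`sigma_mode="joint"` uses the sample standard deviation (ddof = 1) of the
concatenated values, treating the pooled sample as one distribution; the
`"pooled"` mode uses the classical pooled within-group standard deviation
`sqrt(((n-1)s_x^2 + (m-1)s_y^2) / (n+m-2))`, the convention most
tabulated d values follow. The two differ whenever a real group
separation inflates the joint spread, so both are exposed and the mode is
recorded in every result. Joint mode needs `n + m >= 2`; pooled mode
needs two values per group; a zero sigma raises (or, in the bundled
`effect_sizes`, yields `d = NaN` while the sorting statistic is still
returned, since a constant sample has equal medians and hence D_s = 0).

**Sorting statistic D_s.** Groups are first oriented so the larger-median
group plays the role of x; the `swapped` flag records the relabeling, and
a signed convenience value (`ds_signed`, the statistic with the sign of
the median difference in original label order) is derivable from it. If
the medians are equal the statistic is 0 by definition — this also
covers the all-values-identical case, where the ratio would be 0/0.
Otherwise the pooled values are sorted in descending order; the median of
the first n entries and the median of the last m form the denominator.
That denominator equals the maximum of `median(group 1) - median(group 2)`
over every (n, m)-partition of the observed multiset: taking the top n
values maximises every order statistic of group 1 while its complement
minimises those of group 2, and both optima are attained by the same
partition. The test suite re-establishes this computationally against
exhaustive enumeration (`brute_force_denominator`) on hundreds of random
multisets with ties. Consequences, all property-tested:

* `0 <= D_s <= 1`, with 0 iff the medians are equal and 1 under perfect
  separation (`min(x) > max(y)`);
* invariance under group exchange, under affine maps `v -> a v + b`
  (`a != 0`), and under any reordering of tied values;
* `D_s` depends only on the multiset of values and the group sizes.

An ascending sort with the first-m/last-n roles exchanged gives the
identical value; the descending orientation is the package's convention
and a test asserts the equivalence.

**Medians.** Even-count medians are the mean of the two middle order
statistics (the standard convention). Missing values are never silently
accepted by the core: `GroupedSample.from_raw` drops non-finite entries
with a logged count, and the constructors reject NaN/Inf.

**Calibration bands.** Half-open intervals `[threshold, next)`; below the
small threshold is "negligible". Anchors: 0.2 / 0.5 / 0.8 for |d| and
0.2 / 0.45 / 0.7 for D_s. Cohen bands classify the absolute value, D_s
bands the value itself.

## Ordinal extension

For ordered categories the median difference is replaced by a rank
distance: the number of category steps between the group medians, divided
by the number of steps between the first-n and last-m medians of the
jointly sorted (descending by rank) values. A category-valued median is
required for the step count to be an integer, so even-count medians take
the lower of the two middle categories. The statistic is in [0, 1], is 0
iff the group medians land on the same category, is invariant under
order-preserving relabeling, and coincides exactly with the numeric
statistic on consecutive-integer rank codes whenever no half-rank medians
arise (odd group sizes guarantee this; a test checks the agreement).
Distances are computed on level indices only — any numeric coding
shipped with the data is ignored, because the construction is purely
order-based.

## Feature screening

A feature table (subjects × measurements plus one binary group column)
is screened feature by feature: missing values are dropped pairwise per
feature with logged counts, and a feature left without at least one value
per group is skipped with a recorded reason, so retained + skipped always
equals the input feature count. Constant features report D_s = 0 with an
undefined (NaN) d. The group treated as x — the sign convention of d —
defaults to the lexicographically smaller label (so "case"/"control"
orients cases as x) and can be overridden.

The association between the two statistics is summarised by sign-split
correlations: rho over features with d > 0 and rho over features with
d < 0. Features with undefined or exactly-zero d join neither side; a
side with fewer than three features reports NaN with a note rather than
raising. Spearman's rank correlation is the default estimator — the
summary is about monotone agreement, not linearity — with Pearson behind
a flag; the choice is echoed in the output metadata, and actual p-values
are reported as computed by scipy.

Discordant ("V-gap") features are those with `D_s >= 0.2` and
`|d| < 0.2` by default — both thresholds anchored at the small-effect
calibration values, so the flag reads "D_s sees at least a small effect
where |d| sees less than one". Returned sorted by D_s descending.

## Synthetic cohort generator

The generator emulates a case/control morphometric screen with three
feature classes mixed in configurable fractions:

* **null** (default fraction 0.45): both groups N(0, 1).
* **location_shift** (0.40): the case group shifted by an effect drawn
  uniformly from 0.1–1.5 common-SD units with a random sign, so both
  arms of the V-shaped d-vs-D_s scatter are populated from negligible
  through large effects.
* **skew_shift** (0.15): the discordance mechanism. Each group is a
  two-component mixture — a Gaussian bulk (sd 0.03) plus, with
  probability `tail_weight`, a right-tail value `0.1 + Exp(0.1)` —
  mimicking a spike-near-zero-plus-tail curvature-like measurement. The
  case group has tail weight 0.20 versus 0.10 for controls, and the case
  bulk is shifted left by exactly the amount that equalises the two
  population means, so d is near zero by construction while the median
  gap (and hence D_s) is not. Tail weights and bulk scale were fixed by
  a one-off Monte-Carlo calibration targeting |d| ≤ 0.15 alongside
  D_s ≥ 0.25 in the large majority of draws — i.e. a clearly
  discordant feature class — and then frozen.

Defaults are 2000 features × 200 subjects per group (seed 13), which
populates all three regions of the scatter and screens in a couple of
seconds; a full-cohort-sized table (~4800 features × ~2000 subjects) is a
configuration choice, not the default. Determinism: every feature's
stream is seeded by `SeedSequence(seed, spawn_key=(class, index))`, so
identical configs give byte-identical tables and enlarging the table
never perturbs existing features. Feature names encode their generating
class (`null_0000`, …) for stratified checks; column order is shuffled
deterministically from the seed.

What the generator does **not** model: covariate structure (age, sex,
scanner), correlated features (real morphometric measurements are highly
inter-correlated; features here are independent), measurement failure
patterns, or the exact histogram shapes of any particular real
measurement. Tests passing on this synthetic cohort therefore show that
the statistics and the pipeline behave as designed under the intended
data-generating mechanisms — not that any particular real dataset will
yield particular values.

## Numerical choices and degenerate inputs

* Medians via `numpy.median`; sorting via `numpy.sort` (stable ordering
  is irrelevant: the statistic is a function of sorted values only).
* The brute-force partition oracle is guarded at n + m ≤ 14
  (C(14,7) = 3432 partitions); beyond that the sorted-joint denominator
  is the intended computation.
* Equal-median early return avoids the 0/0 case entirely; the
  denominator is provably ≥ the numerator and > 0 whenever medians
  differ, so no other division guard is needed.
* Affine invariance holds to ~1e-12 for well-conditioned inputs; with
  near-tied medians and large offsets, cancellation in `a·v + b` can
  dominate (tests use integer-valued samples where the minimum nonzero
  median gap is 0.5).
* Empty groups, non-finite values, malformed bands and non-positive
  thresholds raise `ValueError` subclasses with explicit messages.

## Problem sizes used in the checks

Exhaustive enumeration uses the 70 size-(4,4) partitions of {1..8};
randomised oracle checks use 500 multisets of total size ≤ 12;
boundedness is additionally sampled at 10^4 random group pairs; the
cohort-level checks use the default 2000 × 400 table and 100 replicates
of the skew-shift feature at 500 per group. These sizes keep the entire
suite under a minute while leaving each claim's evidence exhaustive or
heavily replicated.

## Known limitations

* D_s has no accompanying inference here: no p-values, confidence
  intervals or multiplicity control (deliberately out of scope).
* D_s is blind to differences that leave the medians equal (e.g. pure
  variance differences with symmetric data): the zero rule returns 0.
* The equal-band anchors for D_s (0.2/0.45/0.7) are empirical
  conventions, not derived quantities.
* With tiny groups (n or m of 1–3) the first-n/last-m medians are
  single order statistics and D_s is coarse; it remains bounded and
  well-defined.
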