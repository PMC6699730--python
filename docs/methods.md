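# Methods

This note documents the statistical procedures implemented in `termcal`,
the synthetic data generator used to validate them, the defaults and the
reasoning behind them, and the limits of what the tests demonstrate.

## Calendar data and episode extraction

DHS-style reproductive calendars record one character per month for up to
80 months before the interview. `cal1` holds pregnancy states ('P'),
outcomes ('B' birth, 'T' termination) and contraceptive method codes;
`cal2` holds discontinuation reasons, notably the "became pregnant while
using" code; `cal3` holds union status. Dates are century-month codes
(CMC, months since January 1900). Code sets and string orientation vary by
survey phase, so all parsing is driven by a `CalendarDialect`; the
canonical dialect puts the interview month leftmost with time running
right-to-left and pads pre-calendar positions.

An episode closes at each outcome month; its start is the first month of
the contiguous 'P' run immediately before the outcome. Rules for edge
cases:

* consecutive outcome codes without intervening 'P' are separate
  pregnancies (a multiple birth in one month is a single 'B');
* a trailing 'P' run with no outcome is an ongoing pregnancy and yields no
  episode;
* a run that touches the calendar start cannot be dated (possible left
  truncation) and is dropped, with a logged count;
* a 'P' run longer than eight months before its outcome is capped at a
  nine-month gestation, start adjusted, with a warning.

Classification at the time of pregnancy:

* **use** — when `cal2` is present it is authoritative: the
  became-pregnant-while-using code is looked for at the start month and
  the month before (covering both placement conventions for "the last
  month of use"). Without `cal2`, use is assumed when any method code
  occupies the month preceding the start. Any method counts, since use of
  any method signals an intent to avoid pregnancy.
* **union** — `cal3` at the start month when present; otherwise imputed
  as in-union from the date of first union onward. The source data do not
  carry union dissolution dates in this path, so the imputation cannot
  return a woman to not-in-union; this overstates in-union exposure for
  dissolved unions and is a known approximation.

Selection: episodes whose start lies in the closed window
`[interview − 45, interview − 9]` months. The right bound removes
pregnancies censored before a full-term outcome; with nine-month
gestations the surviving births fall in the 36 months before the
interview, the standard DHS fertility window, which is what makes the
rate derivation below consistent. Age is the imputed age at birth in
completed years — the outcome month for births, start plus nine months
for terminations — grouped into five-year bands with 40-49 pooled;
imputed ages under 15 are excluded. Both window bounds are treated as
inclusive (37 start months); the alternative half-open readings differ
only in one boundary month of exposure.

## Estimation

`T` per stratum is the ratio of weighted terminated pregnancies to all
weighted pregnancies; marginal strata pool weighted counts rather than
averaging sub-stratum probabilities. Confidence intervals are Wilson
score intervals on the **unweighted** counts — a deliberate
simplification that ignores the design effect of clustered sampling and
within-woman correlation of repeat pregnancies. The intervals should be
read as approximate; a design-based variance estimator is out of scope.
Exact-coverage computations show the Wilson interval at n=100 oscillates
between roughly 93.3% and 96.5% true coverage across the realistic range
of `T`, which is the behavior the coverage test pins down at a point
where coverage is essentially nominal (95.05% at T=0.18).

Per-type probabilities `T_IA` and `T_ST` use the same denominator (all
pregnancies), so they add to `T` by construction; they are only defined
for surveys that report the type of termination, and the estimator
refuses mixed input with unknown types rather than silently treating
unknowns as a category.

## Rates

With `T_a` and the age-specific fertility rate sharing the same episode
window, weights and age definition, the odds factor converts births per
woman-year into terminations per woman-year:

```
ASTR_a = PT_a/B_a · B_a/N_a = T_a/(1−T_a) · ASFR_a
```

This is an algebraic identity, not an approximation, when both sides are
computed from the same data — the test suite checks it to 1e-12 against
direct weighted counts on simulated truth. `T = 1` (no births) leaves the
conversion undefined and raises.

The total termination rate cumulates `ASTR` over the reproductive span.
The pooled 40-49 band is given width 10 by default so that the synthetic
cohort interpretation (and `TPR = TFR + TTR` with a standard-band TFR)
survives the pooling; the literal uniform-five convention is available as
`LITERAL_FIVE_WIDTHS` since the aggregation formula is conventionally
written with a constant 5. The general rate carries an explicit per-1000
versus per-woman-year unit flag to prevent silent thousand-fold errors.

## Survey profiles, k-POD, gap statistic, PCA

Each survey is summarized by 16 conditional probabilities: users and
non-users crossed with six in-union age groups and two out-of-union bands
(15-24, 25-49; out-of-union pregnancies are too sparse for five-year
groups). Cells supported by fewer than `min_n = 10` unweighted
pregnancies are set missing rather than letting near-noise estimates
drive the clustering.

k-POD alternates full k-means on a completed matrix with re-imputation of
missing cells from the assigned centroid, judging fit only on observed
cells. Implementation choices: missing cells initialize at observed
column means; the first pass of each restart uses k-means++, later passes
warm-start from the current centroids; iteration stops at an assignment
fixpoint or when the observed-cell objective changes by less than `tol`;
the best of `restarts` runs by observed-cell objective wins. Defaults —
50 restarts, `tol` 1e-8, 200 iterations — are generous because
multi-start is the documented remedy for convergence problems in this
algorithm. Clusters are relabelled 1..k by increasing centroid mean, so
labels are deterministic given a partition. Feature columns with no
observed values at all (possible in small studies) are dropped with a
warning. Clustering operates on the raw probability scale; probabilities
share a scale, and standardization would inflate the noisiest columns.

The gap statistic compares log within-dispersion against reference
datasets drawn uniformly over each observed column's range with the same
missing mask (the simplest reference of Tibshirani's construction; the
PCA-rotated variant is not implemented), clustered with the same k-POD
settings, choosing the smallest k whose gap is within one standard error
of the next. `kmax` is capped below the number of surveys because k = n
zeroes the dispersion.

PCA runs on column-standardized completed profiles (correlation matrix):
for interpreting *patterns*, each probability should contribute equally
regardless of its level. The first dimension is oriented so its loadings
sum positive, making it an overall-level axis; remaining dimensions pin
the sign of their largest loading. Constant columns are dropped with a
warning (the standardization would otherwise divide by a float residue of
zero — treated as constant below sd 1e-12).

## Induced/spontaneous decomposition

Surveys reporting the type of termination contribute two observations
each (users, non-users): the cell's `T` and the induced share of its
terminations. The fractional logit maximizes the Bernoulli-form
quasi-likelihood Σ[y·log μ + (1−y)·log(1−μ)] with μ = expit(b0 + b1·T),
unweighted, by Newton-Raphson to a gradient max-norm of 1e-10, with step
damping and divergence detection for separated data. This likelihood
form is chosen because the model's information criteria are then exactly
`AIC = 2p − 2logL` and `BIC = p·ln(n) − 2logL` on the n observations —
consistent with the published pooled fit summaries — and because
termination-count weighting of the 32 observations is not documented for
the pooled fit; the unweighted form is the reproducible choice, flagged
for sensitivity analysis. Standard errors are information-matrix Wald
errors and inherit the usual quasi-likelihood caveat on
proportion-valued responses.

The decomposition `P(IA) = expit(b0 + b1·T)·T`, `P(ST) = T − P(IA)` adds
up to `T` by construction. With a positive slope the spontaneous
component rises to an interior maximum (about 12% of pregnancies at
T ≈ 0.27 under the frozen coefficients −1.632 and 6.733) and declines at
very high `T` — the competing-risks signature. Frozen-coefficient mode is
the default when no type-reporting surveys are available; refitting is
used whenever they are. Predictions for surveys not reporting the type
use each survey's overall `T`; a per-use-group decomposition is available
by passing the corresponding estimates.

## The synthetic data generator

The generator runs each woman month by month from the calendar start to
the interview: union entry (constant hazard from the 15th birthday),
contraceptive adoption and discontinuation, conception with a
stratum-specific monthly hazard, gestation (nine months for births; a
first-trimester-heavy 1-9 month distribution for terminations), and
outcome. Every completed pregnancy is retained in a truth table with the
same classification fields the extraction stage produces, so recovery is
checked field by field; realized woman-months of exposure by age feed the
rate oracles. Sampling weights are log-normal(0, 0.25²) normalized to
mean one — plausible design-weight dispersion without simulating a
two-stage sample.

Default stratum conditions encode the pooled patterns reported from large
multi-survey DHS analyses: in-union non-user termination probabilities
by age {0.110, 0.093, 0.100, 0.120, 0.150, 0.204} (minimum at 20-24,
maximum in the pooled 40-49 band), a 2.1× multiplier after contraceptive
failure (about 21% versus 10%), a 1.15× multiplier out of union, and an
induced share of terminations equal to expit(−1.632 + 6.733·T) of the
stratum's `T`, i.e. the frozen split model planted as truth. Parameters
the source analyses do not report were fixed once at realistic values:
monthly conception hazards for in-union non-users {0.020, 0.022, 0.019,
0.014, 0.009, 0.003} by age (implying peak ASFRs near 0.26), a 0.2×
hazard under contraception (roughly a 5%-per-year failure rate at peak
ages), 0.15× out of union, method adoption 0.03/month, discontinuation
0.015/month, union entry 0.007/month from age 15. Multi-survey studies
scale the stratum probabilities by survey-level factors between 0.4 and
2.2, emulating the observed spread of survey-level `T` from very low- to
very high-reporting settings.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: two-stage cluster sampling and its design
effects; within-woman correlation of repeat pregnancy outcomes (outcomes
are independent given the stratum); union dissolution; post-partum
amenorrhea and breastfeeding infecundability; recall error, omission and
displacement of events, which in real surveys grow with time before the
interview; heaping of reported gestations. Recovery being exact on
synthetic calendars demonstrates that the extraction logic inverts the
encoding, not that real calendars are accurately reported.

Planted-profile studies for the clustering stage draw 40 surveys around
four archetypes (uniformly low; moderate with a mild age gradient; high
in-union with a strong use differential; very high with a steep age
gradient) with cell noise sd 0.045 — the binomial sd of a cell `T`
estimated from roughly 50-150 pregnancies — and mask 12% of cells at
random, matching the missingness rate the min-n rule produces in
practice.

## Problem sizes and numerical choices

Test and acceptance runs use problem sizes chosen to make the checks
sharp while remaining quick on a single CPU: a 20,000-woman survey for
recovery and estimator checks (about 3,200 in-window pregnancies), 500
replicates for interval coverage, 200 refits for split-model coverage, 40
surveys for clustering with 8 reference draws per gap evaluation, and a
six-survey heterogeneous study of 4,000 women each for the pooled
quantities. Tolerances: rate identities to 1e-12 (pure algebra),
information-criteria identities to 1e-9, Newton gradient to 1e-10, k-POD
objective to 1e-8. Ties in k-means empty-cluster handling follow
scikit-learn's relocation of the farthest points, which matches the
documented re-seed-at-most-distant rule.

## Known limitations

* Variance estimation ignores the survey design throughout.
* The union imputation path cannot represent dissolution.
* The split model is a two-parameter summary of a heterogeneous
  relationship; its outputs are tentative reported shares, an upper bound
  on reported induced abortion where overall reported termination is low,
  and say nothing about completeness of reporting itself.
* Premature births are treated as full-term for windowing purposes; a
  small number of early births just outside the window are therefore
  handled as the window dictates, not gestation-corrected.
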