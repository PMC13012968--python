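# Methods

`pvsignals` implements a case/non-case pharmacovigilance analysis of
spontaneous-report data for a two-drug oncology regimen (an anti-VEGF
antibody, drug A, and an alkylating agent, drug B): cohort construction from
report-level drug roles and indication text, multi-algorithm
disproportionality screening, drug–drug interaction signal analysis,
descriptive time-to-onset (TTO) modelling, and logistic regression of
immune-related adverse-event (IRAE) reporting odds. This note records the
model choices, defaults and numerical decisions.

## Data model

Three flat tables (`reports`, `drugs`, `events`) normalise both supported
dialects: a FAERS-style set of five `$`-delimited files (DEMO / DRUG / THER /
INDI / REAC) and a CVARD-style flat CSV. Drug roles follow the FAERS
enumeration PS/SS/C/I; event terms are MedDRA-style preferred terms supplied
by the data (an optional user term map re-codes verbatim strings; no licensed
hierarchy is shipped). Dates are full (`YYYY-MM-DD`), partial (`YYYY[-MM]`)
or missing; partial dates are *retained at ingestion* and excluded only where
an analysis needs day precision, because date validity is an analysis rule,
not an I/O rule.

Deduplication keeps, per case identifier, the report with the highest case
version, breaking ties by latest receive date and then largest report id (a
total order, hence idempotent). A second probabilistic pass (same sex, age
group, receive date, drug set and event set across case ids) exists but is
off by default: regulatory guidance describes case-version replacement;
anything stronger is a user decision.

## Synthetic-report generator

The generator is first-class, not a test fixture: it emits reports with
role-coded drug mentions, per-term Bernoulli event mentions, Weibull onset
times, demographics, indication text, configurable field-level missingness,
and duplicate case versions — with the injected truth recorded so every
downstream stage can be validated against it.

Default study conditions: group sizes 1 000 / 2 000 / 3 000 / 10 000
(combination, drug-A monotherapy, drug-B monotherapy, background), a 24-term
event catalogue with baseline reporting probabilities graded from 2% (common
GI/haematological terms) down to 0.2% (rare opportunistic infections), all
signal multipliers 1 (a null cohort), onset times Weibull(1, 60 days) unless
configured per (group, term), missingness 45% for therapy start dates, 25%
for onset dates, 60% for weight, 25% for age, 15% for sex (typical of
oncology SRS data, where weight and dates are the emptiest fields), and a 5%
duplicate-version rate. `demo_simulation_config()` layers injected
monotherapy haematological signals and combination-specific interaction
multipliers on top.

Mechanics worth knowing:

* The combination group's event probability is baseline × its own
  multiplier × the *product* of the two monotherapy multipliers × the
  interaction multiplier. Monotherapy signals therefore propagate
  multiplicatively to the combination — a multiplicative null — and the
  interaction multiplier injects precisely the more-than-multiplicative
  component the interaction screen estimates.
* Onset times are continuous Weibull draws rounded half-up to whole days
  with a 1-day floor, as reports record them. The rounding truncates the
  early tail and biases fitted shapes upward by roughly +0.04 at shape 0.7,
  scale 40 — visible in the shape-recovery tests.
* Events are sampled independently per term within a report; no term
  correlation, no drug-name misspellings, no reporting-culture or secular
  trends. Passing tests therefore demonstrate correctness of the statistics
  under a clean generative model, not robustness to real-world coding noise.
* In combination reports the PS role is assigned to either study drug with
  probability 0.5 (recorded in the truth), so exposure classification is
  exercised both ways.

## Cohort construction

Exposure (primary definition): combination = both drugs present with one PS
and the other C; monotherapy = the drug is PS and the other absent;
background = neither drug; everything else excluded. Reports listing *both*
drugs as PS do not satisfy the literal one-PS-one-C combination definition;
the default excludes them, with a switch (`both_ps_policy="combo"`) for
sensitivity analysis. The any-role definition (presence under PS/SS/C/I)
is available as `exposure_mode="any_role"` and is, by construction,
a superset of the primary assignment per group.

Indication restriction: normalised substring containment against a
two-tier dictionary (broad default: glioblastoma, glioblastoma multiforme,
gbm, gliosarcoma, malignant glioma; core: the first two), fully
user-overridable. Reports with missing or non-matching indication text are
excluded before exposure classification, and the flow accounting records
every stage count.

Baseline tables use Pearson chi-square without continuity correction,
*including* unknown categories as their own rows; reporter codes that exist
in only one database's dialect are retained and zero-filled in the other
groups. Both choices are validated by exact reproduction of published
baseline p-values in the acceptance suite.

## Disproportionality statistics

For each (group, term) 2×2 table (a, b, c, d), against either the rest of
the analysis set (default) or only the other study groups:

* PRR = (a/(a+b)) / (c/(c+d)); Pearson χ² of the raw table (no Yates
  correction, the convention under the PRR ≥ 2 ∧ χ² ≥ 4 rule);
  CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
* ROR = ad/bc; CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
* Ω = log₂((a + 0.5)/(E + 0.5)) with E = (a+b)(a+c)/N, an
  observed-to-expected shrinkage statistic: the +0.5 smoothing pulls
  sparse-cell estimates toward 0. Credibility bounds are exact gamma
  posterior quantiles, Ω_q = log₂(G⁻¹(q; a + 0.5, rate 1)/(E + 0.5)) — the
  posterior of a Poisson count under the Jeffreys-type prior implied by the
  smoothing. Several Ω-type estimators circulate; this variant is isolated
  behind `compute_omega` so an alternative can be swapped without touching
  the screen, flags or grades.

Zero cells: Haldane–Anscombe +0.5 on all four cells for PRR/ROR point
estimates and CIs, flagged `corrected`; Ω needs no correction by
construction.

Signal rules (all requiring n ≥ 3): Ω credibility lower bound strictly > 0;
PRR ≥ 2 with χ² ≥ 4; ROR CI lower bound > 1. Consistency: Strong = all
three; Moderate = Ω plus one traditional method; Weak = traditional
method(s) without Ω; an Ω-only flag grades **None** — the published rule set
enumerates no such pattern, and the gap is closed conservatively. Priority:
High = Strong ∧ PRR > 5; Medium = Strong ∧ PRR > 2 or Moderate ∧ PRR > 5;
Low = Moderate ∧ PRR ≤ 5 or Weak.

Multiplicity: screening output is exploratory by design (minimum counts,
shrinkage, multi-algorithm consistency); a Benjamini–Hochberg flag column is
available but off by default.

## Interaction analysis

The analysis set is stratified by exposure to each drug; the (0,0) stratum
is the cohort's background group (neither-drug reports surviving the same
indication restriction — the three study groups alone contain no such
stratum). The interaction OR is the ratio of odds ratios
OR(1,1) / (OR(1,0)·OR(0,1)) taken against the (0,0) stratum, i.e. the
interaction-term OR of a saturated case/non-case logistic model — the
standard multiplicative-interaction contrast. A zero in any of the eight
cells triggers +0.5 on all eight (flagged); a `sparse_warning` marks any row
whose uncorrected event cells fall below 5, because ratio-of-odds-ratio
estimates explode under sparsity and must be read as descriptive.

Priority heuristics: High requires both combination-vs-monotherapy PRRs
≥ 2.0, interaction OR ≥ 3.0 and both monotherapy-vs-background PRR *point
estimates* < 1.5; Moderate requires both combination PRRs ≥ 1.8 or an
interaction OR in [2.0, 2.9]. The published wording attaches a
"CI not including 1" clause to the quiet-monotherapy condition, which is
self-contradictory (a PRR < 1.5 whose CI excludes 1 is an inverse signal);
here the CI condition is applied to the combination comparisons (at least
one CI excluding 1), switchable via `require_combo_ci`.

## Time-to-onset and Weibull shape

TTO = onset date − earliest full-precision study-drug start date, in days;
valid only when both dates are full and the difference non-negative (0 is
valid). Exclusions are attributed to exactly one reason (missing start,
partial start, missing/partial onset, negative interval).

Summaries use type-7 (linear-interpolation) quantiles — the convention that
exactly reproduces the published degenerate rows — switchable for
sensitivity checks. Weibull fits are produced from n ≥ 3 but flagged
`below_threshold` under the pre-specified n ≥ 10, mirroring how published
fit tables print sparse rows rather than suppressing them. Zero-day onsets
are substituted with 0.5 day (counted) so the fit's n matches the summary's.

The MLE solves the one-dimensional profile equation
g(k) = Σx^k ln x / Σx^k − 1/k − mean(ln x) = 0 by bracketed root finding
(bracket [10⁻³, 10³], xtol 10⁻¹²), declaring convergence when
|g(k)| < 10⁻⁸; the scale follows in closed form, η = (Σx^k/n)^{1/k}.
All-equal samples have no root (g < 0 everywhere) and return
non-converged with NaN parameters. The solution is scale-equivariant and is
cross-checked in the tests against an independent MLE
(`scipy.stats.weibull_min.fit` with a fixed zero location).

Shape classification: β > 1.2 later-clustering ("Increasing"),
0.8 ≤ β ≤ 1.2 approximately constant (closed band), β < 0.8 early-clustering
("Decreasing"). No survival modelling is attempted: spontaneous reports
carry no follow-up time for non-cases, so censoring is undefined and
Kaplan–Meier/Cox do not apply.

## IRAE regression

Outcome: the report carries ≥ 1 term from a configurable IRAE list (default:
the immune-related terms the screens target). Covariates are
indicator-coded against fixed references — sex (male), age band (<65; the
finer report age groups are collapsed to <65 / ≥65 / unknown), weight group
(50–100 kg), reporter type (MD) — with regimen as the primary exposure
(reference: drug-B monotherapy). Unknown categories enter as explicit
levels (switchable), since the baseline tables retain them. The secondary
combination-vs-drug-A contrast is obtained by *refitting* with drug-A
monotherapy as the regimen reference: the likelihood is identical and Wald
CIs stay conventional, which coefficient differencing would not give.

Fitting is Newton/IRLS maximum likelihood (statsmodels), tolerance 10⁻⁸,
100 iterations. Separation is handled deterministically: any indicator with
a zero margin in its event × level cross-tab is dropped from the fit *before*
estimation and reported "not estimable" (never a numeric OR); a post-fit
sweep catches divergence (|coef| > 10 with SE > 100) the margin check can
miss. Fit indices: McFadden R² = 1 − ll_full/ll_null, AIC = 2k − 2ll,
BIC = k ln n − 2ll, with the null model refitted on the same observations.

## Problem sizes and tolerances in the test and acceptance suites

Calibration checks use sizes chosen to keep sampling error well inside the
asserted bands on a single CPU: null-screen calibration over 20 seeds at
2 000 reports/group (positive fraction observed well under 1% against a 10%
bound); interaction null calibration over 50 strata datasets at
2 000/stratum (mean log interaction OR within 3 standard errors of 0) and
5× injected interaction detected in ≥ 90% of 50 seeds; Weibull shape
recovery over 100 simulations per true shape at n = 200 (mean absolute
error < 0.1); regression log-OR recovery averaged over five datasets of
n = 50 000 (bias < 0.05). The Monte-Carlo oracle for the Ω credibility
bounds uses 10⁶ gamma draws per table over 20 random tables, compared on
the quantile z-scale with a familywise bound (max |z| ≤ 4, median ≤ 1.5):
a per-comparison 3σ rule over 40 simultaneous comparisons would fail a
correct implementation about 1% of the time, while any formula error
produces |z| in the tens.

## Known limitations

* Reporting rates, not incidence: no exposure denominators exist, and none
  of the statistics estimate risk.
* The generator's independence assumptions (terms within a report, reports
  across the database) understate the correlation structure of real SRS
  data; calibration results transfer to real extracts only qualitatively.
* The Ω variant implemented is one member of a family of shrinkage
  estimators; absolute Ω values are not comparable across variants, though
  signal flags are insensitive to the choice in the regimes tested.
* Drug-name handling is exact-match after normalisation plus an explicit
  synonym map; misspellings and combination products are out of scope.
* The interaction OR inherits the instability of eight-cell odds ratios;
  rows with `sparse_warning` should never be ranked by magnitude.
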