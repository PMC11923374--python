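# Methods

## Eating-occasion construction

The unit of analysis is the *eating occasion* (EO) within a participant-day.
Two definitions are implemented over the same food records:

* **Precise**: one EO per distinct clock time (exact minute equality). No
  merge tolerance is applied at construction — 15- or 60-minute EO-separation
  conventions are treated as *descriptive outputs* of the within-slot
  analysis, not as grouping rules, so the two definitions stay strictly
  nested.
* **Broad**: one EO per occupied meal slot, timed at the slot's fixed
  representative clock time. Since the minute→slot map is a function, every
  broad EO is a union of whole precise EOs; grams and kilocalories are
  conserved exactly under both groupings, and per day
  `count(precise) − count(broad) = Σ_broad (members − 1)`.

The default slot scheme is the archival seven-slot coding convention,
implemented verbatim:

| slot | range | representation |
|---|---|---|
| Overnight | 00:00–06:59 | 06:00 |
| Breakfast | 07:00–09:59 | 08:00 |
| Mid-morning | 10:00–11:59 | 11:00 |
| Lunch | 12:00–14:29 | 13:00 |
| Mid-afternoon | 14:30–16:59 | 17:00 |
| Evening | 17:00–19:29 | 20:00 |
| Late-evening | 19:30–23:59 | 22:00 |

Bounds are inclusive at both ends; the ranges partition the day, which the
`SlotScheme` constructor enforces for any user-supplied scheme. Two
representations deliberately fall outside their own slot (Mid-afternoon →
17:00, which is the next slot's start; Evening → 20:00). They are **not**
recomputed as midpoints: the representations are part of the coding
convention being studied, and the broad-method biases they induce (e.g. a
broad last-eating time that can sit after every precise time in the slot)
are part of the phenomenon, not an implementation error to fix.

## Architecture variables

Per participant-day: frequency (EO count), mean EO size in grams and kcal,
first and last EO time (minutes since midnight), eating window
(last − first; 0 on a single-EO day, the literal duration between first and
last eating), and intermeal interval (mean of consecutive gaps; undefined on
single-EO days). Days are then averaged per participant with equal weight
("all recorded days", no weekday/weekend weighting); the interval averages
only over days where it is defined. A pooled-gaps alternative (all gaps
across days pooled before averaging) was considered and rejected as the
default because the per-day-then-across-days reading matches the daily
framing of the other variables; consecutive gaps telescope, so the daily
mean gap is identically `window/(frequency−1)`.

Clock times are averaged arithmetically on the minute scale. Circular
statistics are unnecessary here: diary days are day-local (no cross-midnight
linking), so all times live on [0, 1439] and means cannot wrap.

## Validity and exclusion rules

Participants (not rows) are the unit of exclusion, applied in order of
precedence:

1. any record with a **missing** consumption time;
2. any record with an **invalid** time (later than 23:59);
3. **partial precise data**: on some day the count of distinct valid precise
   times is below the count of occupied meal slots — impossible under
   complete transcription, since every occupied slot must contain at least
   one distinct time.

Rule 3 can only trigger when slot coding exists independently of the time
column (the archival situation: slots coded first, precise times transcribed
later), so the parser accepts an optional `slot` column; without it, rule 3
is provably vacuous after rules 1–2. Malformed rows (unparseable time
strings, negative amounts) are a parse-time concern, reported with line
numbers and skipped; missing/invalid times are *not* malformed — they parse
into records so the exclusion rules can act on them and be audited.
Validation is idempotent and reported as participant counts that balance
exactly (`n_valid = n_input − Σ dropped`).

## Agreement statistics

* **ICC(3,1)**, the individual-measure two-way mixed-effects *consistency*
  intraclass correlation: from explicit ANOVA sums of squares over
  participants × methods, `ICC = (MS_S − MS_E)/(MS_S + (k−1)MS_E)` with
  k = 2. The 95% CI is the exact F-based Shrout–Fleiss interval
  (`F = MS_S/MS_E` on `(n−1, (n−1)(k−1))` df) rather than a bootstrap — the
  model is named by the convention, the CI method chosen for exactness and
  determinism. The consistency form is invariant to a constant shift between
  methods (asserted by test) but not to rescaling one method.
* **Bland–Altman**: differences are `precise − broad`, so an undercount by
  the broad method appears as a *positive* mean frequency difference. SD
  uses the n−1 denominator; limits are `mean ± z·SD` with z = 1.96 by
  default; the share outside counts pairs *strictly* beyond either limit
  (ties on a limit count as inside — the boundary choice is immaterial for
  continuous data and is fixed for reproducibility).
* **Pearson r** with the Fisher-transform CI
  `tanh(atanh r ± z_{1−α/2}/√(n−3))`.

Pairs where a variable is undefined on either side (interval on all-single-
EO participants) are dropped listwise *for that variable only* and counted —
complete-case analysis per cell, also used for the outcome association
table.

## Within-slot composition

For every broad EO that absorbed ≥ 2 precise EOs, the consecutive sorted
gaps between its member times are recorded; per-EO mean gaps are summarised
per slot as median, IQR and 10th/90th percentiles (numpy's linear
interpolation convention, stated so oracles match). Separation-cutoff
fractions are inclusive on both sides: a 15-min gap counts as "≥ 15 min
apart" and a 60-min gap as "60 min or less". Per-slot EO frequency is the
per-participant mean count of precise EOs per *occupied* slot-day (days
where the slot holds nothing do not dilute the mean; a per-all-days variant
would answer a different question and can be derived from the exported EO
table).

## Synthetic cohort generator

The generator emulates 3-day child food diaries with the structure the
method comparison turns on:

* **Meals**: breakfast, lunch, dinner at Gaussian clock-time anchors —
  defaults (mean, SD) in minutes: 484/30, 765/25, 1075/35 — chosen to put
  the cohort first-eating time a few minutes past 08:00 and dinner in the
  Evening slot.
* **Snacks**: Poisson count per day with participant-level gamma-distributed
  rates (mean 4/day, shape 8). The mean makes the expected precise frequency
  3 + 4 = 7 EOs/day; the gamma mixing adds the between-child heterogeneity
  real cohorts show (without it, all between-person variance is Poisson
  noise and every ICC collapses toward zero). Placement: mid-morning 0.20,
  mid-afternoon 0.30, post-dinner 0.50 — post-dinner snacking is the
  designated merge mechanism, since that is where slot coding combines most
  EOs.
* **Post-dinner gaps**: log-normal, median 30 min, σ = 0.6, truncated to
  15–120 min; successive post-dinner snacks chain from the previous evening
  event, so consecutive within-slot intervals follow the configured gap
  distribution.
* **Sizes**: log-normal grams (meal median 300 g, σ = 0.30; snack median
  90 g, σ = 0.45) times a per-participant log-normal portion multiplier
  (σ = 0.25); kcal = grams × a drawn energy density (meals ≈ 1.1, snacks
  ≈ 2.2 kcal/g) — snacks smaller but denser. Each EO is emitted as 1–4 food
  records (Dirichlet split) to exercise record-level grouping.
* **Outcomes**: TEI defaults to the participant's mean daily kcal; BMI,
  waist circumference and the dietary-pattern z-score come from a
  latent-factor model `y = ρ·z(variable) + √(1−ρ²)·ε`, scaled to realistic
  child means/SDs, with configurable (variable, ρ) targets; TEI can be
  switched to this mode to set an exact target correlation.

Randomness uses one seed sequence per cohort, spawned per participant, so a
participant's diary is invariant to cohort size. `corrupt_times` injects
missing/invalid times with a tamper log for exact reconciliation against the
validation report (a participant with both kinds of tampering is counted
once, missing taking precedence).

**What the generator does not emulate** — and hence what passing tests do
not establish about real diaries: reporting error and underreporting,
weekday/weekend structure, skipped meals, food composition beyond a scalar
energy density, day-to-day within-person correlation beyond shared
participant effects, and any cohort-specific demographic structure. The
simulation demonstrates the *direction* and mechanics of timing-precision
bias and validates the machinery; magnitudes on real data depend on the real
time distributions.

## Problem sizes and numerical choices

Conservation and coarsening identities are asserted exactly (1e-9 absolute
on sums of rounded gram/kcal values); agreement statistics are checked
against independent brute-force oracles at 1e-10 relative tolerance on
small fixtures. Simulation-based checks use 334 participants × 3 days
(≈ 1,000 participant-days) for the exact identities, 500 participants for
the method-difference pattern, and 1,000 for correlation recovery —
comfortably past the point where the qualitative pattern is stable across
seeds. Degenerate inputs are errors, not silent results: empty days at EO
construction, fewer than 3 pairs or zero variance for the ICC, constant
inputs for Pearson.

## Known limitations

* Exact-minute EO identity is itself a convention; data recorded at coarser
  precision (e.g. 5-min rounding) will shift precise-method results.
* The F-based ICC CI assumes the usual two-way ANOVA normality; for heavily
  skewed variables it is approximate.
* Arithmetic clock-time averaging would be wrong for diaries crossing
  midnight; the day-local data model excludes that case by construction.
* The pipeline consumes the dietary-pattern score as a supplied z-score
  column; deriving such scores is out of scope.
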