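# Methods

`mspheno` implements a longitudinal digital-phenotyping analysis for people
with multiple sclerosis: rolling binary prediction of four patient-reported
symptom outcomes from passively sensed smartphone and fitness-tracker
streams, with optional ecological momentary assessments (EMAs). Because no
real cohort ships with the package, a synthetic cohort generator with known
ground truth is a first-class component: every claim the test suite makes
about the pipeline (no leakage, signal recovery, bootstrap calibration,
determinism) is made against cohorts whose generating process is fully
known.

## Outcomes and labels

Four outcomes are tracked, each measured by one validated instrument and
dichotomized at a fixed total-score threshold:

| outcome    | instrument | schedule     | threshold (label = 1) |
|------------|-----------|---------------|-----------------------|
| depression | PHQ-9     | every 2 weeks | total ≥ 5             |
| ms_burden  | MSRS-R    | every 4 weeks | total ≥ 6.4           |
| fatigue    | MFIS-5    | every 4 weeks | total ≥ 8             |
| sleep      | PSQI      | every 4 weeks | total ≥ 9             |

Instrument totals are plain sums of item/component scores (PHQ-9: 9 items
0–3; MSRS-R: 8 domains 0–4; MFIS-5: 5 items 0–4; PSQI: 7 components 0–3).
The MSRS-R and MFIS-5 cutoffs are cohort-median-derived values in the
original analyses; here they are fixed defaults, and
`labels.median_threshold` computes a dataset median when a median-derived
cutoff is wanted instead. Surveys run on a Saturday-anchored calendar: the
anchor is the first Saturday *strictly after* enrollment, and
administration *k* of an outcome with period length *P* weeks falls on
anchor + *kP* weeks, closing the period `[anchor+(k−1)P, anchor+kP)`.

## Synthetic cohort generator

Latent severity for each (participant, outcome) is a participant baseline
(normal, sd `baseline_sd` = 1) plus a stationary AR(1) fluctuation across
periods (persistence `ar1_rho` = 0.6 per outcome, innovation sd
`innovation_sd` = 0.8). The latent cut that defines a positive period is
placed at the normal quantile giving `target_prevalence` (default 0.5)
under the marginal latent sd.

Each day, seven behavior channels are drawn around participant-level bases
and shifted by `effect_sizes[(outcome, channel)] × severity ×
channel_day_sd` — daily steps (base 7000, day sd 2000), home-time fraction
(0.55, 0.15), mean screen-session minutes (5, 2), sleep efficiency (0.88,
0.05), awakenings (2, 1.5), resting heart rate (72, 5), calls/day (6, 2.5).
The default effect sizes are moderate (0.2–0.6 sd) couplings in the
clinically expected directions; `null_effect_sizes()` removes all
couplings and `planted_effect_sizes(outcome)` plants ≥ 1 sd effects on
steps, sleep efficiency and home time (plus smaller screen/call effects)
for a single outcome. Planting is deliberately single-outcome: with
simultaneous effect sets for all four outcomes on shared channels, the
other outcomes' independent severities act as correlated noise on the
channel being used, and recovery experiments measure crosstalk rather than
pipeline sensitivity.

Raw streams are rendered at the collection cadences: heart rate, sleep
state, and steps at 1 sample/min, location at 1 sample/10 min, calls and
screen use as event lists, and EMAs (two 0–4 Likert questions, "depressed"
and "tired") at fixed local prompt times 09:00/14:00/19:00. EMA responses
are active self-reports, so their coupling to same-day severity is a
separate dial (`ema_signal`, default 0.9 Likert points per severity sd;
the "depressed" item tracks depression severity, "tired" tracks fatigue) —
a fully null cohort sets both the behavioral effect sizes and `ema_signal`
to zero. Questionnaire item scores are constructed so the instrument total
crosses its threshold exactly when the period's latent severity crosses
the latent cut (ties configurable, default positive), making ground-truth
labels recoverable by construction.

Missingness is MCAR at whole (sensor, participant, day) granularity
(default rate 0.1/day) and EMA prompts are answered with probability
`ema_compliance` (default 0.8); both are placeholders for unreported
real-world rates and fully configurable. An optional MNAR mode links
deletion odds to participant severity for robustness experiments and is
off by default. All timestamps are naive participant-local datetimes; days
are `[00:00, 24:00)` local; DST is not modeled, because temporal slicing
is defined on the local clock. Regeneration from the same `CohortConfig`
is byte-identical (verified by content hash).

Simplifications relative to real deployments: no device artifacts (clock
drift, duplicate uploads), no relapses, no commute trajectories between
places (location jumps between stay regions), and daily behavior draws are
independent given the period severity. Passing tests therefore demonstrate
correctness of the *pipeline machinery* under the assumed generative
structure — not that real sensor data carry the planted effect sizes.

## Feature extraction

Every sensor's daily features are computed inside 15 *temporal slices*:
{all day, night 00–06, morning 06–12, afternoon 12–18, evening 18–24} ×
{all days, weekdays, weekends}, half-open on the local clock. Since a
calendar day belongs to a day group entirely or not at all, daily features
are computed per (date, epoch) and the day group selects which dates enter
a period aggregate; additive features satisfy the partition property
value(all_day) = Σ value(epoch), which is asserted in tests.

Per-sensor daily features (the instruments' supplementary formulas are not
public; this concrete set covers the named behavioral constructs, and the
redundancy-pruning selection stage tolerates an over-complete set):

- **calls** — n_incoming, n_outgoing, n_missed, total/mean duration;
- **heart_rate** — mean/sd/min/max bpm;
- **location** — stay-points are runs of consecutive samples within 50 m
  of the run's first sample lasting ≥ 10 min (gaps > 30 min break a run,
  preventing teleportation artifacts); stay-points within 100 m merge
  greedily into places; home is the place with the most night-epoch time
  over the whole study. Features: places visited, natural-log place
  entropy and its normalized form, home-time fraction (of stay time),
  travelled distance (haversine over consecutive samples ≤ 30 min apart),
  radius of gyration;
- **screen** — a session is an unlock paired with the next lock,
  attributed to the date/epoch of the unlock; n_unlocks, n_on_events,
  unlocked minutes, mean session length;
- **sleep** — asleep/restless minutes, awakenings (awake runs flanked by
  asleep runs), efficiency = asleep/(asleep+restless+awake) with
  "unknown" minutes excluded from the denominator;
- **steps** — total steps, max rolling 5-min sum, sedentary bouts (≥ 30
  consecutive zero minutes), active bouts (≥ 10 consecutive minutes at
  ≥ 60 steps/min), with runs broken at sampling gaps.

Daily features are averaged over each 2- or 4-week prediction period per
slice (mean over days with any data; a feature is missing when no valid
day exists), together with per-slice valid-day counters. The bulk path is
a vectorized pivot equivalent to the reference single-period aggregation
(equivalence is tested). Two EMA feature types are computed per period:
the *average EMA* (mean over days of the within-day mean per question) and
the *presurvey EMA* (last response per question on the day before the
survey).

## Matrices and missing data

To predict the label closing period *i*, the **action** matrix uses
features from period *i* and the **action+context** matrix concatenates
the same features from period *i−1*; rows without a context period are
dropped from the latter, and context columns equal action columns shifted
by one period within participant (tested as an identity). The missing-data
policy (the original supplementary procedure is not public; this is the
package's own rule): (1) a sensor-slice's features are blanked for a
period when data were present on fewer than `min_valid_day_fraction`
(default 0.5) of the slice's days — row-local, hence fold-safe; (2)
columns missing in more than `max_col_missing_fraction` (default 0.4) of
*training* rows are dropped; (3) remaining gaps are imputed with
training-row medians (median for robustness to skewed behavioral
features). Steps 2–3 are fit per CV training split and applied to its test
split. Rows are retained when some sensors are missing: each per-sensor
model simply lacks the rows where its sensor recorded nothing, and fusion
intersects member rows.

## Models

**Base models.** One model per sensor (and per EMA type): an RBF-kernel
SVM with balanced class weights and Platt-style probability outputs,
validated leave-5-participants-out. Folds partition participants into
groups of 5 (last group may be smaller), stratified by dealing
participants in descending positive-prevalence order serpentine-fashion
across folds. Per fold, the pipeline standardizes on training rows,
applies the missing-data transform, prunes features (drop near-constant
columns; among pairs with |r| ≥ 0.9 keep the first in manifest order; rank
by point-biserial correlation and keep the top 30), and picks C from
{0.1, 1, 10, 100} by inner group-wise cross-validated F1 (ties to the
smallest C; gamma is scikit-learn's `scale`). The grid, inner-split count
and k_max are configuration; none are stated in the original analysis.
Out-of-fold positive-class probabilities are recorded for every sample by
a model that never saw that sample's participant.

**Fusion.** Member models' out-of-fold probabilities are stacked (rows =
intersection of member sample sets) and combined with AdaBoost over
depth-1 decision trees, cross-validated on the same fold plan, tuning only
`n_estimators` (default grid {10, 50, 100, 200}; inner selection is
skipped when a grid has a single element, since there is nothing to tune).
The ablation enumerates every subset of size ≥ 2 of the model universe —
57 combinations for 6 sensors, 120 with an EMA model — and the best
combination per configuration is the out-of-fold-F1 argmax, ties broken
toward fewer members then lexicographically. The majority baseline
predicts each fold's training-majority label (ties predict positive).

**Comparison.** The six final models per outcome ({no, presurvey, average
EMA} × {action-only, action+context}) are compared pairwise (15 pairs × 2
metrics = 30 comparisons) by a paired hierarchical bootstrap: each of
10,000 iterations resamples participants with replacement, then each drawn
participant's periods with replacement, applying the identical index set
to both models; 95% percentile CIs of Δaccuracy and ΔF1 follow. Percentile
(not BCa) intervals match the plain description of the procedure; a flat
mode resampling (participant, period) tuples directly is available behind
a flag since the wording admits both readings. A model is *statistically
better* when ≥ 1 metric's CI excludes zero in its favor and the other
metric's CI does not exclude zero against it (the exact dominance rule
when the metrics disagree is not specified in the source analysis; this
both-metric rule is the package's stated convention). Otherwise the more
parsimonious model wins: lexicographic (EMA burden: none < presurvey <
average, counting EMA only if the EMA member was actually selected;
context burden: action-only < action+context; sensor count). The overall
preferred model is the one never beaten; a cyclic relation falls back to
the lowest parsimony among Pareto-best performers (logged).

## Numerical and degenerate-input conventions

- F1 is reported as 0 (with a degeneracy flag) when no positives are
  predicted nor present; empty prediction sets are errors.
- A single-class training split yields a constant prediction with
  probability 1, logged.
- Dichotomization is `total ≥ threshold`; boundary ties in the generator's
  latent-to-total map go to the positive side by default (configurable).
- Malformed sensor records (negative durations, non-positive bpm, unknown
  enum values) are dropped and logged, never propagated.
- All randomness flows from named seeds (cohort, folds, model, bootstrap)
  carried by `RunConfig`; reruns are bit-identical, including CSV
  artifacts and their manifest hashes.

## Problem sizes used by the test and acceptance suites

End-to-end suites run on desk-scale cohorts chosen as the package's
reference conditions: 20 participants × 12 weeks for the null-leakage and
planted-recovery experiments (the smallest cohort with a meaningful
leave-5-out split and ≥ 100 depression samples), 10 participants × 8
weeks for bit-reproducibility, bootstrap calibration at 1,000 iterations ×
200 replicates. Reduced hyperparameter grids (C ∈ {1, 10}, n_estimators ∈
{20} or {20, 50}, 2 inner splits, 500–1,000 bootstrap iterations) are used
in these suites; they are pipeline configuration, and the library defaults
remain the full grids above.

## Known limitations

- The generator's behavior model is conditionally independent across days
  and channels given severity; real streams have autocorrelated,
  cross-correlated noise and context (weather, work schedules).
- Location rendering has no transit between stay regions, so travelled
  distance and radius of gyration carry less independent information than
  in real data.
- The feature formulas stand in for non-public supplementary definitions;
  entropy bases, cluster radii and bout thresholds are configurable
  constants at the top of `features.py`.
- Real-cohort accuracies from the original study are not reproducible
  here (data not deposited) and are not targets of any test.
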