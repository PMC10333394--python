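# Methods

This note records the models behind `pacuseq`, the defaults they ship
with, and the design choices made where more than one reasonable option
existed. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Outcome and features

The outcome is binary: prolonged PACU stay, `pacu_los >= 180` minutes,
inclusive at the boundary. 180 min is the canonical default because it is
the 75th percentile of stay duration in the population the generator
emulates; `compute_prolonged_threshold` computes the empirical quantile
(linear interpolation between order statistics — conventions differ, so
the choice is fixed and documented) for users who want to re-derive the
cut on their own cohort. On synthetic cohorts the two need not coincide
exactly, which is why the fixed default and the quantile operation are
separate.

Features are strictly preoperative: age, sex, BMI, ASA PS (1–4),
procedure category, scheduled case duration, and 16 binary comorbidity
flags. Categorical features are one-hot encoded with a deterministic
column order; numeric features pass through unscaled (the neural network
standardizes internally — scaling is that family's concern). Each
surgical encounter is one row; repeat patients are treated as independent
cases and the stand-alone splitter is case-level, which mirrors common
practice but is a potential leakage channel on real data with many repeat
patients.

## Synthetic cohort generator

The generator is the package's stand-in for institutional data; its
defaults define the study conditions.

**Marginals.** BMI and scheduled duration are lognormal, age truncated
normal (18–90), each parameterized from a median and IQR
(`sigma = log(q3/q1) / (2 * 0.6745)` on the appropriate scale). Defaults:
age 51 [37, 63] y, BMI 26.5 [23.3, 30.6] kg/m², duration 60 [38, 95] min,
38.4% male, ASA weights (0.193, 0.002, 0.568, 0.237), comorbidity
prevalences between 0.6% (CKD) and 15.1% (hypertension). The printed ASA
mix (0.2% ASA 2 next to 23.7% ASA 4) is atypical for an ambulatory
center and is likely an artifact of its source table; it is kept as the
default and is an ordinary config knob. Comorbidity flags are independent
Bernoulli draws: only marginal prevalences are emulated, not the real
correlation structure (e.g. BMI with OSA), so importance rankings among
the *flags* on synthetic data say little about real data.

**LOS model.** `log LOS = β₀ + β_f·I(female) + β_dur·log(dur/60) +
β_bmi·z(log BMI) + β_age·z(age) + ε`, ε ~ N(0, σ²). A lognormal with
total log-scale SD 0.471 and log-median ≈ 4.43 simultaneously yields
P(LOS ≥ 180) ≈ 0.053, median ≈ 81 below the threshold and ≈ 210 above
it, so the defaults decompose that total: effect sizes β_f = 0.12,
β_dur = 0.30, β_bmi = β_age = 0.10 (systematic SD ≈ 0.255) and residual
σ = 0.396. β₀ = 4.357 was fixed once by `calibrate_intercept`, a
documented numerical search that places the intercept so the simulated
marginal exceedance fraction matches the 5.31% target; the routine is
exported so the search is reproducible. Effects were chosen once, live in
the config, and make female sex and long cases risk factors and
duration/BMI/age the dominant attribution signals.

**OR days.** Per-day case counts are drawn from a weight table with
median 4 and quartiles [3, 6]. Which cases land on a day mimics block
booking: each slot is filled best-fit (from a 60-case waiting window)
toward the count-conditional mean content, reproducing the negative
count–duration correlation of real schedules (a day holds three long
cases or seven short ones) without touching any marginal — cases are
reassigned, never redrawn. Scheduled starts run sequentially from 07:30
with a 25-min default turnover. The 25-min turnover is deliberate: with
zero turnover, median-60-min cases packed back-to-back cannot produce a
realistic number of full days (scheduled content past 15:00) under the
[3, 6] cases-per-day quartiles — simulation puts a hard ceiling near 135
full days per 2,186 cases, versus the ~200 a real center shows — while
25 min, a typical ambulatory room-turnover time, reconciles all three
statistics. One surgeon per day; consecutive weekdays; one master seed
with per-stage substreams so each stage regenerates independently.

## Rebalancing

A sampling "ratio" is always minority/majority **after** the step. SMOTE
appends `round(ratio × n_majority) − n_minority` synthetic rows, each
`x + u(x_nn − x)` with `u ~ U[0,1]` and `x_nn` one of the k = 5 nearest
minority neighbours (Euclidean distance on the encoded, unscaled matrix;
a scaling toggle exists). Interpolated one-hot columns are left
fractional, matching the standard algorithm; a rounding toggle exists.
Under-sampling keeps `round(n_minority / ratio)` majority rows, uniform
without replacement. The combined pipeline runs SMOTE first, then
under-sampling — the order the shipped ratio pairs imply (an under-ratio
of 0.9 is unreachable before oversampling). Shipped pairs
(smote, under): logistic (0.75, 0.9), neural net (0.4, 0.5), xgboost
(0.5, 0.85), random forest (0.8, 0.9), balanced random forest
(0.35, 0.75), balanced bagging (0.4, 0.6). Balancing is applied to
training rows only, and inside cross-validation to the fold-training
portion only; pooled out-of-fold predictions therefore cover exactly the
original training rows.

## Models and evaluation

Registry defaults: logistic C = 6 (L-BFGS); network 1 × 128 ReLU, 100
iterations, batch 64, learning rate 1e-4; XGBoost binary:hinge, column
subsample 0.55, learning rate 0.01, max depth 300, 500 rounds, λ = 1.5;
random forest 500 trees; balanced random forest 2,000 trees at sampling
strategy 0.95; balanced bagging 1,200 trees. A tree depth of 300 is far
beyond what 500 boosting rounds can use at this cohort size — it behaves
as "unbounded" and triggers a config warning, but is kept as shipped and
overridable. The balanced ensembles are implemented directly on sklearn
decision trees: every bootstrap pairs a minority resample with a majority
subsample at the target ratio, so imbalance never reaches the base
learner.

The hinge objective emits margins, not probabilities; risks are the
logistic transform of the margin — a strictly monotone link, so AUC and
within-day ordering are invariant to it (tested). AUC is the rank
statistic with tie correction, checked exhaustively against pair counting
on small sets. Sensitivity/specificity default to a 0.5 probability
threshold (exposed as a flag; no principled threshold is claimed).
Confidence intervals are stratified-bootstrap percentile intervals
(default 2,000 resamples; positives and negatives resampled separately;
the interval is widened, if needed, to bracket the point estimate).
Calibration uses ten equal-count bins of predicted risk (stable sort, so
ties keep input order); the count-weighted mean of observed rates equals
prevalence exactly by construction. Cross-validation is stratified
k-fold with pooled out-of-fold metrics (pooling chosen over per-fold
averaging; documented, not both). Feature attribution uses XGBoost's
exact tree-SHAP contributions where available and AUC-scored permutation
importance otherwise; the output labels which method produced it.
Tree-family training is deterministic given the seed (single-threaded);
network determinism is best-effort via the seeded sklearn MLP.

## Resequencing simulation

An OR day is all cases for one surgeon on one date; it is **full** when
the *scheduled end* of its last case is ≥ 15:00 (an alternative
last-start-≥ 15:00 rule is a config option). Only full days enter the
analysis. The counterfactual assumption is explicit: a case's duration
and PACU LOS are intrinsic to the case and travel with it when moved.
Replayed schedules are rebuilt cumulatively from the day's first start
with configurable turnover; the latest surgery end is permutation-
invariant (computed with an exact sum so the invariance holds in floating
point too). A day is after-hours iff any PACU exit is **strictly** past
19:00 (an exit at exactly 19:00 is in-hours). A day counts as
"resequenced" only when the risk-sorted order differs from historic
*and* at least one case is predicted prolonged at the classification
threshold — the rule is configurable since no single convention exists;
both the day count and the moved-case count are reported. Risk sorting is
stable (ties keep historic position). The 2×2 comparison uses the 1-df
chi-square without continuity correction by default (Yates by flag; on
any decisive table both agree). `brute_force_min_latest_exit`
exhaustively enumerates permutations for days of ≤ 8 cases and serves as
the independent optimality oracle for the longest-tail-first policy.

## Pipeline

`run_pipeline` chains the stages and writes flat CSV/JSON artifacts plus
a run log (seeds, versions). Its split is **day-grouped** by default:
whole OR days are held out together (~80:20 by cases), because the
resequencing stage needs every test day intact — a case-level split
scatters a day's cases across both subsets and leaves nothing to
resequence. The case-level stratified split remains the stand-alone
operation for model benchmarking. The replay turnover defaults to the
cohort's booking turnover so the historic arm reproduces the scheduled
day; both arms always use the same turnover, so the comparison is fair
under any setting.

## Problem sizes and determinism

Default analyses use cohorts of 10,928 cases (≈ 2,500 OR days, ≈ 2,186
held-out cases in ≈ 220 full days); generator calibration checks use
n = 10,000. The test suite exercises smaller cohorts (400–3,000 cases)
and reduced bootstrap counts where the contract under test does not
depend on scale. All randomness flows from explicit seeds; reruns with
the same configuration are byte-identical.

## Known limitations

- Synthetic cohorts have independent comorbidities, a single procedure
  effect of zero, and no intraoperative events; passing tests demonstrate
  the pipeline's contracts, not clinical performance.
- Historic after-hours flags are reconstructed from the schedule replay,
  not from recorded exit times (a recorded-exit column can be supplied to
  the simulator, but the generator does not produce one).
- The resequencing gain on synthetic data (≈ 40% → ≈ 27% of days) is
  smaller than the roughly threefold reductions reported in practice,
  because predicted risk orders a day only as well as the model's
  within-day ranking; the oracle (true-LOS) ordering reaches ≈ 19% on the
  same days (recomputed by the acceptance script), bounding what a better
  model could achieve.
- No multi-OR pooling, PACU bed capacity, staffing-cost model, or
  surgeon-preference constraints.
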