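# Methods

`adhersense` implements a complete multimodal pipeline for predicting
next-day medication adherence from mobile-sensing data. This note
documents the models, the parameters that matter, the synthetic world
the package is tested against, and the numerical and design choices made
where the problem was genuinely open.

## 1. Outcome definition

The outcome source is a MEMS-instrumented pill bottle that timestamps
each opening; opening is treated as a proxy for taking a once-daily
dose. A day is labeled **adherent** when at least one opening that day
follows the previous retained dose by an inter-dose interval inside the
clinically acceptable window **[18 h, 30 h]** (24 ± 6 h), bounds
inclusive. Days with no opening, or whose openings all fall outside the
window, are non-adherent. Choices the interval rule itself does not
determine:

- **Multiple openings per day**: each opening's interval is evaluated
  against the previous retained dose; one qualifying interval makes the
  day adherent. The rule is defined on intervals, not days, so this is
  the faithful lift to daily resolution.
- **First dose day**: excluded (no prior dose, interval undefined), as
  are any grid days before it.
- **Deduplication**: openings within 60 min of the previously retained
  opening are collapsed (earliest kept). Bursts of openings minutes
  apart are almost always one dosing occasion; the window is
  configurable and 0 disables everything but exact-duplicate merging.

## 2. Modality features

**MEMS dosing context** (7 features/day): first-opening clock hour,
morning (< 12:00) and evening (≥ 17:00) indicators, weekend flag,
took-today flag, trailing-7-day sample SD of dose hours (timing
regularity; 0 with < 2 doses in the window), and the current adherent
streak length. The compact dimensionality is why this modality skips
feature selection.

**Wearable** (18 features/day): a *wear minute* is a minute with a
present heart-rate sample — the standard proxy for wrist-worn wear — and
a *valid day* has ≥ 480 wear minutes (8 h); invalid days are dropped
before imputation. Features: wear minutes, total steps, active
(≥ 100 steps/min) and sedentary (< 5 steps/min while worn) minutes,
sleep minutes, resting HR (5th percentile), HR SD/skewness/kurtosis
(kurtosis as the raw standardized fourth moment), lag-1 co-occurrence
homogeneity of the HR series (8 equal-width levels between the day's min
and max; Σ P(i,j)/(1+|i−j|), 1 iff constant), step SD, activity-bout
count and mean length (maximal runs of active minutes, min length 1),
per-day step cosinor mesor/amplitude/acrophase, and a marginal-calories
proxy (0.04·steps + 1.5·active minutes; the device's proprietary field
has no synthetic counterpart). Thresholds are configurable; the
literature names these features without fixing definitions, so the
definitions above are documented package choices.

**Cosinor**: y = M + A·cos(2π(t−φ)/1440 min) is fit by least squares on
a 1/cos/sin basis; A = √(a²+b²), φ = atan2(b,a)/ω wrapped to [0, 24) h.
Amplitudes below 1e-9·max(1,|M|) report acrophase 0 by convention. Fits
are per-day by default (a multi-day series can be passed directly).

**EMA** (13 schematic items): five delivery schedules — daily morning
(09:00, open 4 h), daily evening (19:00, open 5 h), random every 3 days
(19:00, open until the next prompt), biweekly (12:00, open 7 days),
monthly (12:00, open 7 days); every schedule triggers on study day 1.
Responses are merged onto the complete participant × day grid;
unanswered prompts stay missing, late responses are kept but flagged,
duplicate responses to one prompt keep the last.

**Baseline survey**: one static row per participant (age,
self-efficacy, medication beliefs, comorbidity count, baseline mood)
feeding the static model described under "Models" below.

## 3. Imputation

**Wearable (two-stage)**: per participant and column, linear
interpolation across adjacent observed days fills interior gaps;
columns still missing in > 30 % of rows are then dropped (only
leading/trailing gaps survive stage 1, which is the one place the rule
can bind); remaining cells are filled by chained-equation iterative
imputation with a gradient-boosted regressor (scikit-learn
`IterativeImputer` + `HistGradientBoostingRegressor`, 5 rounds,
seeded). Observed cells are never altered. Stress-test reruns pin the
retained column set to the baseline run's so cached models keep their
training schema.

**EMA (two-stage + propagation)**: categorical items take the mode of
the strictly preceding 7 days within participant (ties → most recent
tied value; empty window → participant mode → global mode). Numeric
items use chained-equation imputation with the default linear
(BayesianRidge) estimator, 10 iterations, seeded — deterministic and
matching a defaults-style description. Episodic (random/biweekly/
monthly) items are imputed **on their prompt days only**, then
forward-filled across the response day plus cadence − 1 subsequent days
(3/14/28-day footprints), truncated at the next value. Filling episodic
items on every day at the imputation stage would make propagation a
no-op, so the prompt-day restriction is load-bearing. Daily items are
never forward-filled.

## 4. Sequence dataset

Windows of length L ∈ {2,…,7} stack the feature rows of the L
consecutive calendar days immediately preceding a labeled target day;
every feature therefore strictly precedes its target. Days with any
missing feature (impossible after imputation, asserted anyway) break the
windows that would contain them — dropping, not imputing, partial
windows is the conservative choice. Standardization is *not* applied
here; it belongs inside each training fold.

## 5. Models

**Tier-1 sequence classifier**: a single-layer LSTM over the window with
a logistic output head, implemented in numpy with manual
backpropagation through time and Adam (the environment provides no
deep-learning framework; at this scale — windows of 2–7 days, tens of
features — the hand-rolled implementation trains in milliseconds and is
bit-reproducible). Gradients are verified against central finite
differences in the test suite. Weighted binary cross-entropy with
inverse-class-frequency sample weights handles imbalance; l2 penalizes
the recurrent and output weights; inverted dropout acts on the final
hidden state; early stopping (patience 10, best weights restored)
monitors inner-validation balanced accuracy when a validation split is
available, else training loss. The forget-gate bias initializes to 1.

**Nested LOPO**: outer loop = leave-one-participant-out; inner loop =
grouped 3-fold over training participants (LOPO-within-LOPO would be
quadratic in cohort size for no extra independence). Per inner split, a
100-tree random forest ranks features on the most recent day of each
training window; subset sizes and LSTM hyperparameters are searched
jointly on mean inner balanced accuracy (ties → smallest subset,
earliest grid entry); the winning configuration is refit on the full
outer-training set (re-ranking features there) and scores the held-out
participant. Default grid: units {16,32,64}, dropout {0,0.2,0.5},
l2 {1e-4,1e-3}, subsets {10,20,50}, ≤ 100 epochs. `HyperGrid.reduced()`
(units 16, dropout {0,0.3}, l2 1e-3, subset 8, ≤ 60 epochs) is the
desk-scale default used by the acceptance script and test suite to fit
single-CPU budgets. MEMS skips feature selection. The probability
threshold is 0.5 with ties to the positive class. Per-fold audit records
(training participants, scaler/ranking inputs, chosen config) make the
leakage assertions testable rather than aspirational.

**Static baseline model**: per outer fold, a gradient-boosted
regression tree maps training participants' baseline features to their
mean adherence rate; the held-out participant receives that value,
clipped to [0,1], as a constant daily probability.

## 6. Fusion

FusedProb = Σ_m w_m·p_m with Σ w_m = 1 and w_m ≥ 0 (the sum constraint
alone would allow outputs outside [0,1]). Optimized mode enumerates the
simplex at resolution 0.05 and keeps the vector maximizing training
macro balanced accuracy of the thresholded fused probability, using only
the current fold's training participants' out-of-fold Tier-1
predictions; ties break toward the uniform vector, then
lexicographically — absent evidence, the uniform baseline wins. Uniform
mode fixes w_m = 1/M. Because the uniform vector is on the grid,
optimized training BA is never below uniform training BA.

## 7. Evaluation

Macro balanced accuracy averages ½(TPR_c + TNR_c) over both classes
(for binary labels this equals plain balanced accuracy — an algebraic
identity the tests also assert numerically); it is undefined on
single-class truth and the implementation raises rather than guessing.
Macro F1 averages per-class F1 with the 0-convention for undefined
classes. The majority baseline predicts the modal training class (ties →
positive) and scores exactly 0.50 macro BA on any mixed test set. Its
macro *F1* is often quoted as 0.50 as well, but under the standard
conventions a majority predictor's macro F1 depends on prevalence; the
package treats 0.50 as a reference constant for the BA only and never
asserts it for F1.

Confidence intervals: participant-level percentile bootstrap (resample
participants with replacement, pool, recompute; 1000 resamples, 95 %,
seeded). Participants, not days, are the independent units. Resamples
with single-class pooled truth are skipped. Subgroup reports run the
same machinery per group, flagging single-class or single-participant
groups instead of reporting undefined quantities.

## 8. Missing-data stress tests

Feature cells of the EMA and wearable tables (never MEMS, which defines
the outcome) are masked **before imputation** under (a) MCAR at rates
0.1–0.5 and (b) structured 3-day gaps in 10 % of participant-weeks.
Imputation, windowing and prediction are then re-run with the **cached**
per-fold Tier-1 models and per-fold optimized fusion weights, and the
change in fused macro BA versus the unperturbed run is reported.
Re-using cached models isolates the effect of test-time missingness
(and fits the compute budget); it does not measure robustness of the
*training* procedure to missingness. In stress reruns the masked
feature tables are already ordinal-encoded, so categorical EMA items are
re-imputed as numeric ordinals — a deliberate simplification.

## 9. The synthetic world

The generator is a stated world, not a tuning dial; its defaults are
fixed once and the tests live with the consequences.

Latent structure per participant: a random intercept b_i ~ N(0, 0.5²)
and an AR(1) mood/symptom state s_d (coefficient 0.7, stationary SD 1).
Next-day adherence is Bernoulli with

    logit p_d = logit(β₀) + b_i + 2.5·ρ·(a_{d−1} − β₀)
                + β_w·1[weekend] + γ·s_d

with base rate β₀ = 0.75, persistence dial ρ = 0.6, state effect
γ = 0.8, and β_w the log-odds shift that lowers the probability by the
weekend penalty (0.10) at the base rate. Day 1 uses the stationary rate
for the persistence term. Degenerate base rates 0 and 1 short-circuit to
deterministic adherence so edge-case contracts hold exactly. Adherent
days emit one opening at N(08:00, 1 h²); non-adherent days emit none
(spurious openings are configurable, default off, since opening proxies
ingestion).

Wearable: steps/min = A·(1 + cos(2π(t−14 h)/24 h))·exp(0.15·s_d) + AR(1)
noise, clipped at 0 and zeroed during sleep (23:00–07:00); A = 10
steps/min. HR = 60 + 5·cos(shifted circadian) + 0.05·steps + 2·s_d +
AR(1) noise. With probability 0.15/day a contiguous 2–20 h non-wear gap
blanks the channels; long gaps produce genuinely invalid (< 8 h) days.
EMA items are noisy linear readouts of s_d on a 1–5 scale, plus a
categorical side-effect severity item (ordinal cut of −s_d), a
forgot-medication item tied to the day's true adherence, and a
biweekly missed-dose count over the trailing 14 days; prompts go
unanswered with probability 0.25. Baseline features are noisy readouts
of b_i. Rationale for every default: it is the simplest value that makes
the corresponding published signal (recency, weekend disruption, morning
dosing, mood, circadian structure) recoverable at desk scale; none was
revisited after seeing test outcomes.

What the generator does **not** emulate: device sync duplicates and
firmware gaps, sleep-architecture detail (time-in-bed equals sleep
minutes synthetically), EMA delivery-app behavior, informative
(non-MCAR) missingness, and enrollment/demographic structure. A green
test therefore establishes that the pipeline recovers planted structure
under idealized noise — not that it matches any particular study's
numbers, which derive from private data.

## 10. Numerical notes and limitations

- Determinism: every stochastic component takes a seed; per-fold seeds
  derive via `SeedSequence` so folds are independent but reproducible.
  Single-threaded numpy gives bit-identical LSTM fits.
- The labeled adherence rate sits below the latent rate by construction:
  a dose following a missed day has a ~48 h interval and is labeled
  non-adherent even though a dose was taken. This is the interval rule
  working as specified, not a bug.
- `nested_lopo` cost scales as participants × inner folds × grid size ×
  LSTM fit; the reduced grid exists to keep full runs in minutes. Use
  the full default grid for anything publication-grade.
- The fusion grid at resolution 0.05 enumerates C(n+19, 19)-ish vectors;
  fine resolutions with > 4 modalities get expensive.
- Bootstrap CIs are percentile (no BCa correction) and assume
  exchangeable participants.
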