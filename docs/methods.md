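# Methods

## Problem and pipeline

`schedetect` asks whether the *spatiotemporal* behavior of a rat in an open
chamber — where it goes, how fast, and where it pokes its head — carries
enough signal to recover the stimulus schedule it is living under, without
observing any lever press or other designated operant. The pipeline has four
stages:

1. **simulate** — synthetic 20-min sessions in a 92 × 92 cm chamber with a
   water dispenser at the midpoint of each wall, under four schedule
   conditions (fixed/variable time × fixed/variable space) and a no-schedule
   (extinction) condition;
2. **featurize** — eight per-session measures: head-entry counts at the four
   dispensers, traveled distance, SD of frame-by-frame speed, location
   entropy, and the Kullback–Leibler divergence from the previous session's
   occupancy distribution (optionally interresponse-time mean and SD);
3. **detect** — three binary classification tasks (schedule vs. none,
   fixed vs. variable space, fixed vs. variable time) under 12-fold
   leave-one-subject-out cross-validation with four algorithms;
4. **stats** — signal-detection outcomes (d′, criterion c, sensitivity,
   specificity; 2AFC d′ from accuracy for single-class test sets), exact
   one-sample Wilcoxon signed-rank tests per model with a Bonferroni-corrected
   threshold, and a tie-corrected Friedman test per task.

## Schedules

Time component: FT delivers water every 30 s; VT draws inter-delivery
intervals uniformly with replacement from the constant-probability list
{3, 7, 13, 21, 31, 47, 88} s, whose arithmetic mean is exactly 30 s. The
uniform-with-replacement choice is one of two defensible readings (per-session
shuffled blocks being the other); the constant-probability property of the
list, not the draw order, is what flattens the momentary delivery rate, and
the draw mode is configurable. Every delivery is preceded by a 3-s tone and
followed by 3 s of water access. Space component: fixed space sends every
delivery to one dispenser; variable space draws a dispenser uniformly at
random per delivery. Extinction sessions have no tones and no deliveries.

The default design is 12 subjects, 3 per condition (S1–S3 fixed/fixed,
S4–S6 fixed-space/VT, S7–S9 variable-space/FT, S10–S12 variable/variable),
30 schedule sessions followed by 10 extinction sessions per subject, 6,000
position samples per session at 5 Hz.

## Locomotion model

The movement model is invented — its only job is to produce the
condition-dependent statistical structure the classification presumes, not
rat kinematics. It is a two-state switching walk at the 0.2-s step:

* **explore**: isotropic Gaussian steps (SD `step_noise_explore`, default
  3 cm/step) with reflecting walls;
* **dwell**: exponential pull toward a target dispenser
  (`approach_gain` = 2.5 s⁻¹) plus smaller noise (1 cm/step). The dwell
  target is the fixed dispenser under fixed space and a random dispenser
  under variable space or extinction.

Transitions follow per-second hazards (`dwell_rate` = 0.12,
`leave_rate` = 0.10 under a schedule; 0.02/0.25 under extinction, so
exploration dominates). During a tone and the access window the agent is
pulled to the active dispenser regardless of state. Head entries fire as a
thinned Poisson process (0.8 s⁻¹ under schedules, 0.15 s⁻¹ under
extinction) only while the agent is within 6 cm of a dispenser.

These defaults were chosen once, for face-valid separation: extinction
sessions are diffuse (location entropy ≈ 4.4 nats, near the ln 100 ≈ 4.6
ceiling) with few entries; fixed-space sessions concentrate near one
dispenser (≈ 1.9 nats); variable-space sessions split time across four foci
(≈ 3.3 nats). FT and VT produce nearly identical session-level statistics
by construction — aggregate features integrate out interval spacing — so the
time-component task is hard, mirroring the negative finding in the real
experiment this emulates. What passing tests show is that the pipeline
recovers planted condition differences; they say nothing about effect sizes
in real rats, tracking noise, individual differences, or learning dynamics
within a session, none of which are modeled.

Reflecting (rather than clamping) walls avoid boundary pile-up. Per-session
seeds derive from `SeedSequence(master, crc32(subject), phase, session)`, so
any subset of sessions is reproducible independently.

## Features

Occupancy grids bin each sample's 0.2 s into one of 10 × 10 = 92/10-cm cells
(half-open cells, top/right chamber edge closed; binning divides by the cell
size so exact boundary coordinates land deterministically). Location entropy
is −Σ p ln p in nats with 0·ln 0 = 0. Divergence is D(P‖Q) of the current
session P from the predecessor Q; by default both grids receive one sample
period (0.2 s) of pseudo-occupancy per cell before renormalizing, so the
value is always finite, while `smoothing=0` enforces the strict support
condition and raises where P has mass off Q's support. The predecessor is
the subject's immediately preceding raw session, crossing the
schedule→extinction phase boundary; the very first session is compared with
itself (divergence 0) and falls inside the five excluded sessions anyway.

The speed series pads the first frame (v₀ := v₁) so a 6,000-sample session
yields 6,000 speed points; the 5,999-difference variant is available. Speed
SD uses divisor n (population form); at n = 6,000 the distinction is
negligible but it is recorded in run metadata. Sessions with fewer than two
head entries (common in extinction) impute IRT mean = session length and
SD = 0, flagged, preserving "a long time between responses" without dropping
rows.

## Classification

The first five sessions of each phase are excluded for stability, leaving
25 schedule + 5 extinction rows per subject for the schedule task and 25
rows per subject (extinction dropped) for the component tasks. Each fold
trains on 11 subjects and tests on the 12th. Minority-class training rows
are oversampled with replacement to balance (e.g. 55 extinction rows → 275);
features are then z-scored with statistics of the balanced training set and
the same transform is applied to the test subject (per-fold statistics by
default — no leakage; a "global" mode exists because the original analysis
may have standardized once over all rows). The
oversample-then-standardize order reflects the distribution the classifier
actually sees; the opposite order is a config option.

Classifiers (scikit-learn): L2 logistic regression (liblinear, C = 1), SVC
with RBF kernel (variance-heuristic width, C = 1), 100-tree random forest
with entropy splits and √p feature subsampling, and a dense 8→5→3→1 network
(ReLU hidden, sigmoid output, binary cross-entropy) trained with adam and
stopped once the loss improves by less than 0.001 for 10 consecutive epochs,
capped at 1,000 epochs. The network uses mini-batches (min(200, n)): the
loss-plateau early-stop rule presumes several gradient updates per epoch,
and with one full-batch step per epoch at the default learning rate it
halts while the loss is still high. No hyperparameter was tuned.

## Outcomes and tests

For the schedule task each fold yields a 2 × 2 confusion matrix →
sensitivity, specificity, and d′ = z(H) − z(F), c = −(z(H) + z(F))/2, with
the 1/(2n) rule replacing proportions of 0 and 1 before the z-transform.
That rule is pinned by reproduction of the published per-rat outcome grid:
43 of the 48 published (rat × algorithm) d′/c cells follow from their
printed sensitivity/specificity to two decimals under it. The remaining five
printed cells are internally inconsistent — pairs of cells with identical
inputs print different outputs, and one subject's two c cells are transposed
— so no correction rule can reproduce them; the corresponding acceptance
tests are left failing by design and the discrepancies are treated as print
errors.

Component tasks have single-class test sets (each rat saw one schedule), so
only accuracy is defined; d′ comes from the 2AFC closed form √2·z(p) with
the same extreme clamp — the continuous function underlying the published
2AFC lookup tables.

The Wilcoxon signed-rank test is exact: zeros dropped, average ranks for
tied magnitudes, and the p-value from the full 2ⁿ sign-assignment null
computed by convolution over doubled ranks (so midranks stay integral). The
reported W is the rank sum of the less frequent sign. The Friedman statistic
uses within-block average ranks with the standard tie-correction divisor;
its p-value comes from the χ²(k−1) reference distribution by default, with
an exact (k!)ⁿ permutation mode for small n used by the oracle tests. The
familywise threshold is α/m = 0.05/12 ≈ 0.0042 (commonly quoted as .004).

## Numerical and scale choices

* All 480 sessions of the default experiment simulate in a few seconds; the
  full pipeline (simulate → stats, 144 fold evaluations) runs in well under
  a minute, and the test suite uses a reduced 8 + 7-session experiment where
  full scale is not required.
* Random-forest vote ties at exactly 0.5 predict positive (scikit-learn's
  argmax convention); the network thresholds its sigmoid output at 0.5.
* Degenerate inputs are defined: single-sample sessions have distance 0,
  constant feature columns z-score to 0 with a warning, fully tied Friedman
  matrices return statistic 0, and an all-zero Wilcoxon sample raises.
* A known artifact of the 2 × 2 design under leave-one-subject-out: in the
  FT-vs-VT task the held-out subject's space condition is underrepresented in
  its own time class within the training set, which can push accuracy
  systematically *below* chance on synthetic data where space dominates the
  feature space. This is the space–time interaction confound, visible here
  because the synthetic FT/VT conditions are otherwise identical.

## Limitations

The simulator has no learning, no satiation, no within-session drift, no
tracking noise, and homogeneous subjects within a condition; classification
on it is easier than on real recordings. The exact Wilcoxon is quadratic in
total rank mass and intended for the n ≤ 20 regime it is used in. The exact
Friedman mode enumerates (k!)ⁿ orderings and refuses sizes beyond ~500k
permutations.
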