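# Methods

`weakfoot` implements a wearable plantar-pressure pipeline for fall-risk
screening in older adults: step-level sliding-window augmentation, weak-foot
centre-of-pressure (COP) features, a Distribution Difference Index (DDI)
with an adaptive trainable threshold that flags "recessive weak foot" (RWF)
individuals, and a two-stage classifier with individual-type-specific
branches, evaluated leave-one-subject-out (LOSO). This note records the
model, the defaults, and the design decisions taken where the design was
genuinely open.

## Steps and windows

A *step* is one foot-contact event of either foot, counted across both feet
in onset order. Contacts are detected per foot as runs of per-foot total
force above a threshold `eps`; a contact only ends once the force stays at
or below `eps` for at least `min_dur_ms`. Real insoles never read exactly
zero during swing, so `eps` defaults to 2% of the recording's
95th-percentile total force and `min_dur_ms` to 50 ms; both are exposed in
`RunConfig`. The first two detected steps are discarded as gait start-up.

A walk of `S` steps is augmented into `N = floor((S − L)/s) + 1` windows of
`L` consecutive contacts advanced by a stride of `s = 10` steps. Each window
spans the frames from the onset of its first step to the end of its last
step and carries both feet's signals over that span, so sequential analysis
inside a window is well defined. When `(S − L)` is not divisible by `s` the
trailing remainder is dropped (flooring is the only loss-free completion).
Within a window, a foot's trajectory and pressure profile use only the
frames of that foot's steps *inside* the window; this keeps partial
neighbouring contacts — which begin or end during double support — from
leaking in, an artifact that otherwise depends on the parity of the window
start.

## Weak foot and COP features

Per frame, the COP of one foot is the force-weighted mean of its sensor
coordinates (mm; per-foot local frame, y growing heel → toes). Per window,
the foot with the smaller anterior-posterior COP standard deviation
(`Std_y`) is the *weak foot* (ties go to the right foot, matching the `≥`
branch of the selection rule).

Three feature families are computed per window (14 features):

* **Foot-level sway** of the weak-foot trajectory: `Std_x`, `Mean_x`,
  `Std_y`, `Mean_y`; `MRD`/`SRD` (mean/SD of the resultant distance from
  the trajectory centroid); `TOTEX` (total excursion, the summed
  point-to-point path length); `CCA` (95% confidence-circle area,
  `π(MRD + 1.645·SRD)²`, the standard posturography formula — the name
  alone does not pin a formula, so the conventional one is used).
* **Left/right symmetry**: `SIM` (cosine similarity) and `JSD`
  (Jensen-Shannon divergence, natural log, hence bounded by ln 2) of the
  two feet's per-sensor mean-pressure distributions, sensors aligned by
  index (anatomically homologous positions); `GA = 100·|ln(m_L/m_R)|` on
  the per-foot mean stance durations.
* **Temporal consistency** of consecutive weak-foot steps: `SSIM`/`SJSD`
  apply the same two comparators to consecutive same-foot per-step sensor
  profiles and average; `GIC` is the mean absolute log-ratio of
  consecutive stance durations.

All standard deviations are population (ddof = 0) statistics: the windows
are short and every use is descriptive. A feature that cannot be computed
(all-zero distribution, missing side) is NaN and listed in the vector's
`missing` field — never silently zero. The exact comparator formulas are
this package's documented defaults; the family semantics (symmetry,
consistency) are fixed but each comparator is swappable via the registry.

## Distribution Difference Index

For one subject, let `v_1..v_N` be the z-scored 5-D weak-foot vectors of
the windows at one length. The full-connection distance

    d_L = (1 / (N(N−1))) · Σ_{i≠j} ‖v_i − v_j‖

is the mean Euclidean distance over all ordered pairs (the normaliser
`Σ(N−1)` is read as `N(N−1)`, the only reading under which the statistic is
an average of pairwise distances). The DDI is `d_l / d_h` with `d_l`
computed at the short default length of 20 steps and `d_h` at a long
length (default 130 steps) that serves as the subject's own baseline and
removes overall gait-variability differences between individuals.
Intermittent expression of the high-risk gait inflates short-window
dispersion far more than long-window dispersion, so RWF subjects occupy
the high-DDI tail. The adaptive threshold is

    T = DDI_min + (DDI_max − DDI_min) · α,   α ∈ [0, 1],

with the extremes taken over the training subjects (optionally replaced by
μ ± 3σ clipped to the observed range); a subject is RWF iff DDI > T
(strictly). Features are z-scored with training-set statistics per window
length before the distance: the five features carry heterogeneous units and
the `d_l/d_h` ratio does not cancel per-feature scales.

**Default weak-foot vector.** The five-feature vector is configurable; the
default is `(Std_y, Mean_y, Std_x, MRD, TOTEX)`. The sway trio
`Std_y/MRD/CCA` (and largely `TOTEX`) are nearly collinear — all track the
rollover extent — which would make the distance effectively one-dimensional
and its short/long ratio heavy-tailed across subjects. `Mean_y`, the
anterior-posterior COP position, responds monotonically and nearly linearly
to changes in push-off, adding a stable second dimension; `Std_x` covers
the medial-lateral axis.

**Test time.** A held-out subject's DDI uses its own unlabelled windows and
the training-set scalers; if a recording is too short for the configured
long length, the longest length still yielding two windows is used, with a
warning.

## Two-stage model

**Stage one** fits the threshold on the training subjects' DDIs and, for
each α on the grid 0.14–0.40 in steps of 0.02 (14 values), partitions the
subjects into RWF/DWF branches, runs feature selection per branch, and
scores the partition by the overall training accuracy of a fixed
default-hyperparameter surrogate classifier (SVC by default). The score is
*subject-grouped cross-validated* (two repeats of 3-fold), not in-sample:
in-sample scoring is degenerate here because a smaller branch always fits
itself better, so the search would always collapse to maximal flagging.
For each branch the score takes the better of the branch-specific view and
the pooled view, matching the fallback behaviour below. The best α wins;
ties go to the smallest α.

**Feature selection** is three-phase. Phase 1 keeps features with a
two-sample t-test p < 0.05 between classes (relaxing to the smallest
p-values, with a warning, if nothing survives). Phase 2 runs eleven
selectors, each nominating five features: five filters (ANOVA-F,
quantile-binned mutual information, point-biserial correlation, variance of
the min-max-scaled column, a Relief-style nearest-hit/nearest-miss margin),
four wrappers (forward and backward greedy search around two light base
learners — a least-squares linear discriminant and a nearest-centroid
rule), and two embedded selectors (L1-penalised logistic regression,
random-forest importance). Phase 3 ranks features by nomination count
(ties by t-test p) and picks the cardinality with the best subject-grouped
CV accuracy of a lightweight linear discriminant. The selector identities are this package's
documented stand-ins; the 5/4/2 family structure is fixed.

**Stage two** selects and tunes a classifier per branch from the
seven-candidate roster — logistic regression, SVM, k-NN, decision tree,
random forest, gradient boosting, AdaBoost — via subject-grouped stratified
CV, tuning exactly two hyperparameters each (cost/iterations for LR,
neighbours/leaf size for k-NN, cost/gamma for SVM, depth/leaf size for the
trees, estimators/learning rate for the boosters). Windows of one subject
are near-duplicates (stride-10 overlap), hence the grouping. The
cost-sensitive candidates use class-balanced weights: routing
systematically unbalances the DWF branch (it loses mostly high-risk
subjects), and the misclassification-cost hyperparameter is the natural
lever for that.

**Fallbacks and optional guards.** A branch with fewer than three subjects
or a single class uses the pooled model (trained on all training
subjects); otherwise the branch trains its own model. Two optional guards
can additionally require evidence before a branch leaves the pooled model
(`RunConfig.gate_margin >= 0` demands a surrogate-CV edge on the branch
members plus a final-model CV win; `specialize="rwf_only"` restricts
adaptation to the RWF branch). Both are off by default: they stabilise
the two-stage-versus-pooled comparison but also neutralise the
random-reference ablation, because they protect *any* partition — genuine
or random — from harmful branch training. See "Known limitations".

**Evaluation** is LOSO: for every held-out subject all scalers, thresholds,
feature selections and classifiers are refit on the rest; the held-out
subject is routed by its own DDI and its windows are voted (majority, ties
to the high-risk call — screening favours sensitivity). High risk is the
positive class; accuracy, F1, sensitivity and specificity come from the
subject-level confusion counts.

## Synthetic gait generator

The generator emits bilateral 16-sensor insole recordings (4×4 grid per
foot, coordinates in mm) with known ground truth. Defaults emulate a
two-minute corridor walk: cadence 110 steps/min, 222 steps, 100 Hz
sampling, stance duration 1.1× the step period (≈ 10% double support).
Each stance emits per-row half-sine pressure bursts that progress heel to
toe, producing a posterior-to-anterior COP rollover within every step. A
faint full-sole pedestal keeps the total force positive across the whole
contact (its COP sits at the sole centroid, so burst-dominated frames are
barely moved).

The *high-risk gait* is anterior rollover attenuation: in the high-risk
state the weak foot's anterior rows fire earlier and weaker (onset and
amplitude scaled by `1 − (1−a)·anteriority`, default `a = 0.5`), which
directly shrinks the anterior-posterior COP excursion that the weak-foot
rule keys on. Phenotypes: `DWF_LR` (never high-risk, labelled low-risk),
`DWF_HR` (always high-risk), `RWF` (two-state Markov switching between
steps, labelled high-risk). The RWF chain has exit rate 0.1 from the
high-risk state and a stationary occupancy of 0.35: episodes are temporally
clustered and cover about a third of the walk, so short windows are
near-pure (high dispersion) while long windows carry a diluted mixture
whose features sit near the class boundary — the constellation the DDI and
the two-stage routing exist to exploit.

Within-walk variability has four components, each needed for realistic DDI
behaviour:

* per-step motor jitter (amplitude CV and burst-onset SD, 2%),
* a deterministic *fatigue morph*: push-off onsets delay and amplitudes
  decline linearly over the walk along a fixed "tired push-off" axis, with
  a per-subject slope. A smooth monotone trend is what anchors every
  subject's short-window/long-window dispersion ratio: both distances
  become proportional to the slope, which cancels in the DDI;
* a small slow AR(1) rollover wander,
* sensor noise inside bursts and per-step amplitude noise.

Between subjects, a fixed *gait signature* (per-sensor amplitude factors,
per-row onset offsets; SD 0.28/0.084) gives every feature genuine
between-subject spread. This matters twice: it makes the two classes
overlap at realistic (~80–90%) classification accuracy instead of being
trivially separable, and it keeps cohort-level z-scales dominated by
between-subject variance so that within-subject dispersions are commensurable
across subjects.

What the generator does **not** model: biomechanically validated force
profiles, spatiotemporal stride geometry (step length/width), IMU channels,
sensor drift or saturation, and any label noise in the high/low-risk
assignment. Passing tests therefore demonstrate that the pipeline recovers
the programmed structure under controlled conditions, not clinical
performance on real cohorts.

## Study sizes and numerical choices

* DDI recovery study: cohorts of 16 + 16 + 8 (DWF-LR/DWF-HR/RWF) subjects
  at the full default walk (222 steps, `d_20`/`d_130`), ten seeds.
* Two-stage LOSO study: the mixed cohort of 32 subjects (16 low-risk, 8
  persistent high-risk, 8 RWF — 25% RWF prevalence, balanced labels) with
  102-step walks, long/stage-two length 80, inner tuning CV of 2 grouped
  folds, and the reduced hyperparameter grids above. These sizes are the
  package's own scaled study design; the pipeline semantics are identical
  at larger sizes.
* The inner sklearn loops run under
  `config_context(assume_finite=True, skip_parameter_validation=True)`;
  inputs are validated once at the module boundary.
* Randomness flows from a single run seed through `numpy.SeedSequence`;
  derived seeds stay below 2³¹.
* Degenerate inputs: a cohort with identical DDIs collapses the threshold
  (warning); an all-identical long-window set raises a degenerate-gait
  error rather than returning an infinite DDI; undefined metrics (zero
  denominators) warn and report 0.

## Known limitations

* `d_h` is estimated from heavily overlapping windows (stride 10 at length
  130), so it has few effective degrees of freedom; the DDI is therefore a
  noisy ratio at the single-subject level and is meant for cohort-level
  thresholding, not individual diagnosis.
* The eleven selector identities and the comparator formulas are
  documented stand-ins for a family structure whose original members are
  not published in full.
* The two-stage gain over the pooled model depends on cohort composition;
  with few or single-class RWF-flagged subjects the model (by design)
  reduces to the pooled baseline.
* On the synthetic study cohort the two-stage model does not systematically
  beat the pooled baseline: the flagged training set is usually
  single-class (all high-risk), so the RWF branch cannot train a
  classifier and RWF test subjects are scored by the pooled model either
  way, while retraining the cleaned DWF branch shifts its boundary
  relative to the near-threshold subjects that routing sends it at test.
  The random-reference ablation does reproduce: replacing the DDI with a
  random number costs about four accuracy points on the same cohorts. Both
  facts are measured by the acceptance suite and reported by
  `scripts/acceptance.py`.
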