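# Methods

This note documents the model, the synthetic study conditions, the
numerical choices and the known limitations of `ppa_subtypes`.

## Model

### w-scores

For every region of interest (ROI) an ordinary least-squares regression is
fitted on the control cohort (one baseline row per control):

    volume ~ intercept + sex + age + TIV + scanner

Categorical covariates (sex, scanner type) enter as fixed effects with
reference-level dummy coding; the reference is the first level in sorted
order. The residual SD uses the degrees-of-freedom correction
sqrt(SSR/(n−p)); consequently in-sample control w-scores have mean exactly 0
and, when their SD is computed with the same n−p convention, scale exactly 1.
The w-score of any visit is −(observed − predicted)/SD, the sign flip making
atrophy positive so that severity thresholds (1, 2, 3) are ascending.
Follow-up visits are scored with the baseline-fitted control model using the
visit's own age and scanner values. An unseen scanner level at scoring time
is an error, never an extrapolation. No mixed-effects or site-harmonization
model is used — scanner is a plain covariate.

### Threshold-event progression model

Events are (ROI, threshold) pairs enumerated ROI-major with thresholds
ascending; the primary configuration (19 ROIs × thresholds 1,2,3) has 57
events, the sensitivity configurations (2,4,5) and (1,3) have 57 and 38.
A subtype's trajectory for ROI b is piecewise linear in stage k: 0 at stage
0, exactly z_r at the stage of event (b, z_r), and rising toward a ceiling
z_max = max(threshold) + 2 at the final stage (5 for thresholds (1,2,3),
7 for (2,4,5)). The ceiling keeps the trajectory strictly increasing after
the top threshold in every supported configuration; within a biomarker,
threshold events are constrained to ascending order in all sequences and
MCMC proposals, since a monotone trajectory cannot cross thresholds out of
order. Per-biomarker noise is σ_b = 1 in w-score units (the data are already
unit-scaled by construction); it is configurable but never estimated.
The stage prior is uniform over 0..N including stage 0, which must be
reachable for the not-subtypable rule.

### Fitting schedule

* C = 1: greedy event-relocation ascent (move one event to the best of all
  N positions, re-sorting that biomarker's thresholds; ties break to the
  smallest index) from `n_restarts` random sequences (default 25).
* C > 1: initialize from the fitted (C−1)-model by bipartitioning the
  hard-assigned subjects of each subtype, refitting each half as a single
  sequence, and keeping the best initialization by data log-likelihood
  (`n_split_attempts` bipartitions per subtype, default 5). The first
  bipartition of each subtype is pattern-based — 2-means on the subjects'
  unit-normalized w-score rows, which separates co-clustered progression
  patterns regardless of severity and lands EM in a far better basin than
  chance — and the remaining attempts are random halves. Then EM:
  responsibilities → fraction updates (mean responsibility) →
  responsibility-weighted greedy re-optimization of each sequence, one
  relocation pass per EM iteration, until the log-likelihood gain falls
  below 1e-6 (default cap 100 iterations). Responsibilities below 1e-10 are
  zeroed in the M-step, which changes the objective by < 1e-8 per subject
  and lets each subtype's pass touch only its own subjects.
  The per-iteration log-likelihood trace is stored in the fit log, and the
  test suite asserts it never decreases. EM is run from the *two* best
  initializations (by initialization likelihood) and the better final
  optimum is kept, followed by a final M-step run to convergence at the
  last responsibilities: a single EM run occasionally settles in a basin
  where two planted subtypes stay merged, and since held-out likelihood
  differences between adjacent C are only a few units per fold, model
  comparison is only as good as the worst per-fold fit.
* MCMC: Metropolis over sequences — pick a subtype, move one random event to
  a uniform random position (a symmetric proposal on canonical sequences),
  accept with min(1, likelihood ratio). Mixture fractions stay at their EM
  values. All iterations are retained (the chain starts at the EM optimum,
  so no burn-in is discarded); default 10 000 iterations.
* CVIC: subjects are split into K random folds (default 10); per fold a
  model hierarchy is fitted on the training folds and each candidate C is
  scored by −2 × held-out log-likelihood of its point-estimate sequences;
  CVIC(C) sums over folds and the smallest C attaining the minimum wins.
  Averaging held-out likelihood over MCMC samples instead of point
  sequences would also be defensible; point sequences are used because the
  choice is simpler and deterministic.

All stochastic steps take explicit seeds recorded in fit logs and run
manifests; reruns are bit-identical.

### Assignment

The joint posterior P(c, k | x) ∝ f_c · L(x | S_c, k) is computed in log
space. The default two-step rule assigns stage = argmax of the stage
posterior marginalized over subtypes, then (if stage > 0) subtype = argmax
of the subtype posterior marginalized over stages; stage-0 subjects are
flagged not subtypable with no subtype. A joint-argmax mode is available
(`mode="joint"`); the marginal rule can differ from it by one stage in
near-tie cases. External cohorts are w-scored against their *own* controls
and then assigned with the trained model unchanged.

### Subtype similarity

The positional variance matrix of a subtype holds the MCMC frequency of
each event at each stage position (doubly stochastic by construction).
Two models are compared by the unweighted mean over events of the Hellinger
distance between corresponding rows (a `max` aggregation is available);
H(P,Q) = sqrt(1 − Σ √(p_i q_i)), 0 for identical distributions, 1 for
disjoint support. Two randomized reference schemes are shipped and the
scheme identifier is stored with every reference value:

* `delta-permutation` (default): pairs of independent uniform random
  orderings of the event set, compared as delta matrices. Positions collide
  with probability 1/N, so the reference mean converges to 1 − 1/N
  (≈ 0.9825 for 57 events). The within-biomarker threshold-order constraint
  is deliberately *not* imposed here: the null represents arbitrary
  orderings, and the constraint would skew event-position marginals away
  from uniform, destroying the closed form.
* `permuted-data`: fits single-sequence models to per-biomarker row-permuted
  copies of a supplied w-score matrix (destroying inter-regional
  correlation) and compares seeded refits; slower but data-driven.

### Longitudinal consistency

Subjects unsubtypable at baseline are excluded from all stability
denominators; a follow-up that falls to stage 0 is excluded from the
stability fractions and counted in a separate sink column of the transition
matrix. Subtype stability compares baseline with the first follow-up
(lowest visit index above baseline); stage outcomes (advanced / same /
regressed, with "same" meaning exact equality) and the same-or-advanced
staging-consistency fraction are computed among stable-subtype subjects
only; a second fraction over *all* usable pairs (subtype held or not) is
reported alongside it, since the two denominators answer different
questions and are easy to conflate. Multi-visit summaries (always-same-subtype, monotone-stage) cover all
visits of subjects with at least two.

## Synthetic study conditions

The generator emulates a single-centre PPA volumetric study. Defaults are
the study conditions and are not adjusted per analysis:

| parameter | default | meaning |
| --- | --- | --- |
| n_patients / n_controls | 270 / 121 | cohort sizes |
| subtype fractions | (82, 71, 59, 52)/264 | planted subtype mix |
| ROIs / thresholds | 19 / (1, 2, 3) | 57 events |
| stage distribution | uniform over 0..57 | baseline stages (≈2% at stage 0) |
| noise_sd | 1.0 | patient residual noise, w-score units |
| σ_ROI | 5% of the ROI intercept | control residual SD, mm³ |
| covariate effects | age −25 mm³/yr, male +200 mm³, TIV 0.005, scanner offsets (0, +80, −120) | forward model |
| follow-up | 137/270 subjects, interval 1.1 ± 0.6 yr (truncated > 0) | longitudinal design |
| stage_rate | 5 stages/yr | ~57 stages over a ~11-year course |
| scanner change | probability 0.2 per follow-up | cross-scanner follow-ups |

Volumes are generated by inverting the w-score definition —
volume = intercept + covariate effects − σ_ROI·(abnormality + noise) — so
the scoring regression recovers the planted abnormality exactly in the
infinite-control limit (`true_covariate_model` exposes that limit for
tests). Four planted orderings mirror the qualitative subtype anatomy:
temporal-first, insula-first, temporoparietal-first and frontal-first, with
each ROI's three threshold events interleaved six ranks apart so early
regions progress through severities while later regions begin to decline.
Diagnosis labels are drawn per subtype from a mix dominated by svPPA in the
temporal-first subtype and nfvPPA in the frontal-first subtype, so
subtype-phenotype contingency analyses have realistic structure.

What the generator does *not* emulate: regional covariance of atrophy
beyond the planted sequence (noise is independent across ROIs), non-Gaussian
residuals, scanner-by-region interactions, measurement floor effects, or
diagnosis-dependent stage distributions. Passing tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to real-data violations of them.

## Numerical choices and degenerate cases

* Residual SD guarded at 1e-8 (noise-free regressions would otherwise
  divide by zero).
* Greedy/EM tie-breaks: first index wins; improvements must exceed 1e-10.
* Likelihood evaluation expands ‖w − E‖² = ‖w‖² − 2w·E + ‖E‖² so the
  subject × stage grid is one matrix product; log-sum-exp is max-shifted.
  The hot loops (candidate trajectories, stage marginals) are numba
  kernels; a pure-numpy trajectory implementation is kept as the public
  API and the two are cross-checked in tests.
* At the terminal stage every trajectory equals z_max, so all subtypes are
  indistinguishable there: subjects capped at stage N revert to the
  largest-fraction subtype. Longitudinal tests therefore use baseline
  stages in the identifiable range (1..40) for exactness checks.
* Finite control samples shift MAP stages by ±1 even at noise 0 (residual-SD
  estimation error); exactness tests use the generative covariate model,
  sampling-error tests use fitted controls.

## Problem sizes used in the shipped checks

The test battery and `scripts/acceptance.py` use scaled-down schedules
chosen for desk-scale runs on one CPU: recovery fits use 4 greedy restarts,
3 split attempts per subtype (the 2-means bipartition plus two random),
8-pass split refits, an EM cap of 30 iterations and 1000 MCMC iterations;
cross-validated selection (5 folds, candidates 1–5) uses 2 restarts,
2 split attempts, 6-pass split refits and an EM cap of 15; the enumeration
oracle uses a 3-biomarker instance with 60 subjects and 30 000 MCMC
iterations; the randomized reference uses 2000 pairs. Production runs
should prefer the library defaults (25 restarts, 5 split attempts, 10-fold
CV, 10 000 MCMC iterations). At desk scale the CVIC margin between the
true subtype count and its neighbour is a few log-likelihood units per
fold, so selection is reliable only insofar as every per-fold fit is
near-optimal — the best-of-two EM schedule exists for exactly that reason.

## Known limitations

* The subtype count search stops at 5 candidates by default.
* σ_b is fixed, not estimated; heteroscedastic regions would need the
  distribution-fitted event variant, which is out of scope.
* CVIC with few folds on modest cohorts has selection variance; the
  Hellinger similarity with the randomized reference is the intended
  complementary parsimony check.
* The same-or-advanced longitudinal fraction under the default noisy
  conditions sits near the mid-80s in percent: with unit noise the stage
  posterior is ~3 stages wide while a 1.1-year interval advances ~5.5
  stages, so ~12–17% of stable-subtype pairs appear to regress. This is a
  property of the model geometry at these noise settings, not an
  implementation artifact.
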