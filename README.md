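# ppa-subtypes

Data-driven discovery of spatiotemporal atrophy subtypes in primary
progressive aphasia (PPA), as a tested, reusable Python pipeline.

PPA is a family of language-led dementias (semantic, non-fluent/agrammatic
and logopenic variants, plus unspecified cases) whose regional atrophy
patterns overlap across clinical diagnoses. This package implements the
unsupervised subtype-and-stage approach to that problem: instead of grouping
patients by diagnosis, it infers *neuroanatomical subtypes* — clusters of
patients sharing one cumulative sequence in which brain regions become
abnormal — together with each patient's *stage* along their subtype's
sequence.

## The model

**w-scoring.** Each regional volume is converted to a covariate-adjusted
z-score against a control cohort:

    w = −(observed − predicted) / σ_resid

where *predicted* and *σ_resid* come from a per-region OLS regression of
control volumes on sex, age at scan, total intracranial volume and scanner
type. The sign flip makes atrophy positive and increasing.

**Threshold events.** For each of B regions, severity thresholds
z₁ < z₂ < … (default 1, 2, 3 in w-score units) define *events*; with 19
regions and three shared thresholds the model has N = 57 events. A subtype
c is a permutation S_c of the event set; at stage k ∈ {0..N} the expected
abnormality of region b is a piecewise-linear trajectory through 0 at stage
0, z_r at the stage of event (b, z_r), rising toward a ceiling z_max after
the last threshold. The likelihood of a w-score row x at stage k is a
product of Gaussians N(x_b; E_b(k), σ_b²) with σ_b = 1, and subjects follow
a mixture over subtypes (fractions f_c) with a uniform stage prior:

    P(x) = Σ_c f_c · 1/(N+1) · Σ_k Π_b N(x_b; E_b^{S_c}(k), 1)

**Inference.** Sequences are fitted by greedy event-relocation ascent from
random restarts; C-subtype models are initialized by splitting one subtype
of the fitted (C−1)-model and refined by EM; the number of subtypes is
chosen by the cross-validation information criterion (CVIC: sum over folds
of −2 × held-out log-likelihood); posterior uncertainty over sequences
comes from a Metropolis sampler (no burn-in is discarded — the chain starts
at the EM optimum). Patients are staged by the subtype-marginal stage
posterior; stage-0 patients are "not subtypable". Subtype progression
patterns are compared by the mean Hellinger distance between the
event-position posteriors of their positional variance matrices, with a
randomized-model reference value H₀ for calibration.

Because volumetric cohorts of this kind are not openly deposited, the
package ships a first-class synthetic-cohort generator
(`ppa_subtypes.synthetic`) that emulates the study structure — four planted
subtypes with temporal-first / insula-first / temporoparietal-first /
frontal-first orderings over 19 ROIs, covariate effects, control cohort,
and follow-up visits with advancing stage — so every stage of the pipeline
is testable end to end against known ground truth.

## Worked example

```python
import numpy as np
import ppa_subtypes as pps

# a small synthetic study: 60 patients in 4 subtypes, 80 controls
cfg = pps.SyntheticConfig(n_patients=60, n_controls=80, seed=123)
table, truth = pps.generate_dataset(cfg)

controls = table[table.group == "control"]
patients = table[table.group == "patient"]
W = pps.compute_wscores(patients, pps.fit_control_model(controls))

es = cfg.event_set()                     # 19 ROIs x thresholds (1,2,3)
print(es.n_events)                       # -> 57

model = pps.fit(W, es, n_subtypes=4,
                config=pps.FitConfig(n_restarts=4, seed=0))
model = pps.mcmc(W, model, n_iter=2000, seed=1)

rec = pps.assign_table(W, model)
print(rec.subtypable.mean().round(3))    # fraction beyond stage zero
rep = pps.stability_metrics(rec)
print(round(rep.overall_stability, 2))   # baseline->follow-up subtype stability
print(round(rep.staging_consistency, 2)) # same-or-advanced staging fraction

ref = pps.randomized_reference(es, n_pairs=2000, seed=2)
print(round(ref.h0_mean, 4))             # -> 0.9824 (null similarity, ~1 - 1/57)
```

On this seed the example prints `57`, `0.989` subtypable, stability `0.73`,
staging consistency `0.86` and H₀ `0.9824`: nearly every patient is beyond
stage zero, most keep their subtype at follow-up (a small cohort fitted
with few restarts keeps some label noise), stages mostly advance, and the
null reference shows what *unrelated* orderings look like.

The same analysis is available from the shell:

```bash
ppa-subtypes simulate --seed 1 --n-patients 60 --out cohort.csv
ppa-subtypes wscore --input cohort.csv --out w.csv
ppa-subtypes fit --wscores w.csv --n-subtypes 4 --out model.yaml
ppa-subtypes assign --model model.yaml --input w.csv --out assigned.csv
ppa-subtypes run-all --out results/ --seed 1   # full pipeline + manifest
```

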