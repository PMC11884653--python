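"""Synthetic PPA cohorts with planted subtype, stage and covariate structure.

The generator emulates the structure of a single-centre PPA volumetric study:
~270 patients split across four planted atrophy subtypes, 121 controls, 19
regions of interest, covariate effects of age, sex, total intracranial volume
and scanner, and follow-up scans at 1.1 +/- 0.6 year intervals with advancing
disease stage.  Volumes are produced by *inverting* the w-score definition,

    volume = intercept + covariate effects - sigma_roi * (abnormality + noise),

with ``sigma_roi`` the control residual SD (5% of the regional intercept by
default), so the w-scoring regression is exactly invertible and every
downstream stage is testable end-to-end without external data.  The planted
abnormality of a subject at true stage k is the piecewise-linear trajectory
value of their subtype's event sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import ConfigurationError, EventSet, build_event_set, trajectory_matrix

__all__ = [
    "ROI_NAMES",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_truth_sequences",
    "generate_truth",
    "generate_cohort",
    "generate_followups",
    "generate_dataset",
]

#: The 19 regions of interest, named after the regions implicated in PPA.
ROI_NAMES = (
    "left_temporal_pole", "right_temporal_pole", "left_inferior_temporal",
    "left_middle_temporal", "left_superior_temporal", "left_insula",
    "right_insula", "left_hippocampus", "left_amygdala", "right_amygdala",
    "left_parahippocampal", "left_anterior_cingulate",
    "left_temporoparietal_junction", "left_superior_parietal",
    "left_precuneus", "left_precentral", "left_inferior_frontal",
    "left_middle_frontal", "left_orbitofrontal",
)

#: Plausible mean regional volumes (mm^3) used as regression intercepts.
ROI_BASELINE_MM3 = {
    "left_temporal_pole": 7600.0, "right_temporal_pole": 7800.0,
    "left_inferior_temporal": 11200.0, "left_middle_temporal": 12500.0,
    "left_superior_temporal": 10900.0, "left_insula": 7100.0,
    "right_insula": 7200.0, "left_hippocampus": 3200.0,
    "left_amygdala": 1600.0, "right_amygdala": 1650.0,
    "left_parahippocampal": 4100.0, "left_anterior_cingulate": 5200.0,
    "left_temporoparietal_junction": 11600.0, "left_superior_parietal": 10800.0,
    "left_precuneus": 9700.0, "left_precentral": 12300.0,
    "left_inferior_frontal": 10300.0, "left_middle_frontal": 13900.0,
    "left_orbitofrontal": 9200.0,
}

SCANNERS = ("SiemensTrio3T", "SiemensPrisma3T", "GESigna1.5T")
_SCANNER_P = (0.45, 0.35, 0.20)
DIAGNOSES = ("svPPA", "nfvPPA", "lvPPA", "PPA-nos")

# Region priority per planted subtype: temporal-first, insula-first,
# temporoparietal-first and frontal-first orderings (the qualitative S1-S4
# patterns), with the regions each subtype spares placed last.
_SUBTYPE_ROI_ORDERS = (
    ("left_inferior_temporal", "left_temporal_pole", "left_middle_temporal",
     "left_superior_temporal", "left_amygdala", "left_hippocampus",
     "right_temporal_pole", "left_parahippocampal", "right_amygdala",
     "left_insula", "right_insula", "left_temporoparietal_junction",
     "left_anterior_cingulate", "left_precuneus", "left_superior_parietal",
     "left_orbitofrontal", "left_inferior_frontal", "left_middle_frontal",
     "left_precentral"),
    ("left_insula", "right_insula", "left_hippocampus", "left_parahippocampal",
     "left_amygdala", "right_amygdala", "left_anterior_cingulate",
     "left_middle_temporal", "left_superior_temporal", "left_inferior_temporal",
     "left_inferior_frontal", "left_orbitofrontal", "left_middle_frontal",
     "left_temporoparietal_junction", "left_precentral",
     "left_superior_parietal", "left_precuneus", "left_temporal_pole",
     "right_temporal_pole"),
    ("left_temporoparietal_junction", "left_middle_temporal",
     "left_superior_temporal", "left_superior_parietal", "left_precuneus",
     "left_inferior_temporal", "left_temporal_pole", "left_anterior_cingulate",
     "right_insula", "left_insula", "left_inferior_frontal",
     "left_middle_frontal", "right_temporal_pole", "left_orbitofrontal",
     "left_precentral", "left_hippocampus", "left_amygdala",
     "left_parahippocampal", "right_amygdala"),
    ("left_precentral", "left_inferior_frontal", "left_middle_frontal",
     "left_orbitofrontal", "left_anterior_cingulate", "left_insula",
     "right_insula", "left_superior_parietal", "left_temporoparietal_junction",
     "left_precuneus", "left_superior_temporal", "left_middle_temporal",
     "left_hippocampus", "left_inferior_temporal", "left_amygdala",
     "right_amygdala", "left_parahippocampal", "left_temporal_pole",
     "right_temporal_pole"),
)

# Diagnosis mix per planted subtype (svPPA, nfvPPA, lvPPA, PPA-nos),
# matching the observed subtype-by-diagnosis composition of a real PPA
# cohort: S1 dominated by svPPA, S4 by nfvPPA, S2/S3 mixed.
_DIAGNOSIS_GIVEN_SUBTYPE = (
    (71, 3, 1, 7),
    (15, 34, 18, 4),
    (4, 21, 31, 3),
    (4, 45, 1, 2),
)


@dataclass
class CovariateEffects:
    """Forward-model covariate effects on volume, in mm^3 per unit."""

    age: float = -25.0  # mm^3 per year
    sex_male: float = 200.0  # offset of male vs female
    tiv: float = 0.005  # mm^3 per mm^3 of TIV
    scanner: dict = field(default_factory=lambda: {
        "SiemensTrio3T": 0.0, "SiemensPrisma3T": 80.0, "GESigna1.5T": -120.0})


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the discovery-cohort conditions: 270 patients with subtype
    fractions (82, 71, 59, 52)/264, 121 controls, 19 ROIs with thresholds
    (1, 2, 3), unit-variance residual noise, 137/270 of patients followed up
    at 1.1 +/- 0.6 year intervals.
    """

    n_patients: int = 270
    n_controls: int = 121
    roi_names: tuple = ROI_NAMES
    thresholds: tuple = (1.0, 2.0, 3.0)
    subtype_fractions: tuple = (82 / 264, 71 / 264, 59 / 264, 52 / 264)
    truth_sequences: np.ndarray | None = None  # (C, N) event ids; default planted orders
    stage_distribution: np.ndarray | None = None  # over 0..N; default uniform
    noise_sd: float = 1.0  # patient residual noise, w-score units
    sigma_roi_fraction: float = 0.05  # control residual SD as fraction of intercept
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    followup_interval_mean_sd: tuple = (1.1, 0.6)  # years
    followup_fraction: float = 137 / 270
    n_followup_visits: int = 1
    stage_rate: float = 5.0  # stages per year
    scanner_change_prob: float = 0.2
    diagnosis_given_subtype: tuple | None = None  # rows: subtype, cols: DIAGNOSES
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.covariate_effects, dict):  # round-trip from YAML/manifest
            self.covariate_effects = CovariateEffects(**self.covariate_effects)
        frac = np.asarray(self.subtype_fractions, dtype=float)
        if abs(frac.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"subtype_fractions sum to {frac.sum()}, not 1")
        if np.any(frac < 0) or np.any(frac > 1):
            raise ConfigurationError("each subtype fraction must lie in [0, 1]")
        thr = np.asarray(self.thresholds, dtype=float)
        if np.any(thr <= 0) or np.any(np.diff(thr) <= 0):
            raise ConfigurationError("thresholds must be strictly ascending and positive")
        if self.stage_rate < 0:
            raise ConfigurationError("stage_rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_fractions)

    def event_set(self) -> EventSet:
        return build_event_set(self.roi_names, self.thresholds)

    def resolved_sequences(self, event_set: EventSet | None = None) -> np.ndarray:
        es = event_set or self.event_set()
        if self.truth_sequences is None:
            return default_truth_sequences(es, self.n_subtypes)
        seqs = np.asarray(self.truth_sequences)
        for s in seqs:
            if not np.array_equal(np.sort(s), np.arange(es.n_events)):
                raise ConfigurationError("each truth sequence must be a permutation of the event set")
        return seqs

    def resolved_stage_distribution(self, n_events: int) -> np.ndarray:
        if self.stage_distribution is None:
            return np.full(n_events + 1, 1.0 / (n_events + 1))
        p = np.asarray(self.stage_distribution, dtype=float)
        if p.shape != (n_events + 1,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("stage_distribution must be a probability vector over 0..N_events")
        return p / p.sum()


def default_truth_sequences(event_set: EventSet, n_subtypes: int = 4,
                            threshold_spread: float = 6.0) -> np.ndarray:
    """Planted event sequences from the subtype region-priority orders.

    Events are ordered by ``roi_rank + spread * threshold_index``: a region
    hit early progresses through its severity thresholds while later regions
    are only beginning to decline, giving interleaved, well-separated but
    realistic orderings.  Supports up to four subtypes over the default ROI
    set; other ROI sets get rotations of the name list as priority orders.
    """
    if n_subtypes > 4:
        raise ConfigurationError("default planted sequences support at most 4 subtypes")
    names = event_set.biomarker_names
    seqs = []
    for c in range(n_subtypes):
        if all(r in names for r in _SUBTYPE_ROI_ORDERS[c]) and len(names) == 19:
            priority = _SUBTYPE_ROI_ORDERS[c]
        else:
            priority = names[c * (len(names) // max(n_subtypes, 1)):] + names[: c * (len(names) // max(n_subtypes, 1))]
        rank = {names.index(r): i for i, r in enumerate(priority)}
        thr_index = np.zeros(event_set.n_events)
        for b in range(event_set.n_biomarkers):
            ev = event_set.events_of(b)
            thr_index[ev] = np.arange(ev.size)
        score = [rank[int(event_set.event_biomarker[e])] + threshold_spread * thr_index[e]
                 for e in range(event_set.n_events)]
        seqs.append(np.array(sorted(range(event_set.n_events),
                                    key=lambda e: (score[e], rank[int(event_set.event_biomarker[e])], e))))
    return np.asarray(seqs)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-subject subtype/covariates and per-visit stages."""

    subjects: pd.DataFrame  # subject_id, true_subtype (1-based), age, sex, tiv, scanner, diagnosis, scan_year
    visits: pd.DataFrame  # subject_id, visit_index, true_stage, age, scanner, scan_year, interval
    sequences: np.ndarray  # (C, N) planted event orderings
    event_set: EventSet
    config: SyntheticConfig

    def stage_of(self, subject_id: str, visit_index: int) -> int:
        v = self.visits
        row = v[(v.subject_id == subject_id) & (v.visit_index == visit_index)]
        return int(row.true_stage.iloc[0])


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream]))


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw per-subject subtype, baseline stage, covariates and diagnosis."""
    es = config.event_set()
    seqs = config.resolved_sequences(es)
    C = config.n_subtypes
    rng = _rng(config, 1)
    n = config.n_patients

    subtype = rng.choice(C, size=n, p=np.asarray(config.subtype_fractions)) + 1
    stage_p = config.resolved_stage_distribution(es.n_events)
    stage = rng.choice(es.n_events + 1, size=n, p=stage_p)

    diag_p = config.diagnosis_given_subtype
    if diag_p is None:
        if C == 4:
            diag_p = _DIAGNOSIS_GIVEN_SUBTYPE
        else:
            diag_p = tuple((1.0,) * 4 for _ in range(C))
    diag_p = np.asarray(diag_p, dtype=float)
    diag_p = diag_p / diag_p.sum(axis=1, keepdims=True)
    diagnosis = [DIAGNOSES[rng.choice(4, p=diag_p[s - 1])] for s in subtype]

    age = np.round(rng.normal(66.1, 7.9, n).clip(40, 92), 1)
    sex = np.where(rng.uniform(size=n) < 122 / 270, "F", "M")
    tiv = np.round(rng.normal(1.45e6, 1.3e5, n).clip(1.0e6, 1.9e6), 0)
    scanner = rng.choice(SCANNERS, size=n, p=_SCANNER_P)
    year = rng.integers(1998, 2020, n)

    subjects = pd.DataFrame({
        "subject_id": [f"P{i:04d}" for i in range(n)],
        "true_subtype": subtype, "age": age, "sex": sex, "tiv": tiv,
        "scanner": scanner, "diagnosis": diagnosis, "scan_year": year.astype(float),
    })
    visits = pd.DataFrame({
        "subject_id": subjects.subject_id, "visit_index": 0, "true_stage": stage,
        "age": age, "scanner": scanner, "scan_year": year.astype(float),
        "interval": 0.0,
    })
    return SyntheticTruth(subjects, visits, seqs, es, config)


def _volumes(config: SyntheticConfig, es: EventSet, abnormality: np.ndarray,
             age, sex, tiv, scanner, rng, noise_sd: float) -> np.ndarray:
    eff = config.covariate_effects
    b0 = np.array([ROI_BASELINE_MM3.get(r, 8000.0) for r in config.roi_names])
    sigma_roi = config.sigma_roi_fraction * b0
    n = len(age)
    noise = rng.normal(0.0, 1.0, size=(n, es.n_biomarkers)) * noise_sd
    scan_off = np.array([eff.scanner.get(s, 0.0) for s in scanner])
    vol = (b0[None, :]
           + eff.age * np.asarray(age, dtype=float)[:, None]
           + eff.sex_male * (np.asarray(sex) == "M").astype(float)[:, None]
           + eff.tiv * np.asarray(tiv, dtype=float)[:, None]
           + scan_off[:, None]
           - sigma_roi[None, :] * (abnormality + noise))
    return vol


def generate_cohort(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Regional volume table for all patient visits in ``truth`` plus controls.

    Patient abnormality at true stage k is the trajectory value of the
    planted subtype sequence at k, plus Gaussian noise of SD ``noise_sd``;
    control rows have expected w-score zero with unit residual noise.
    """
    es = truth.event_set
    for col in ("age", "sex", "tiv", "scanner"):
        if col not in truth.subjects.columns or truth.subjects[col].isna().any():
            raise ConfigurationError(f"truth is missing covariate {col!r}")
    rng = _rng(config, 2)
    trajs = {c + 1: trajectory_matrix(es, truth.sequences[c]) for c in range(len(truth.sequences))}

    v = truth.visits.merge(truth.subjects[["subject_id", "true_subtype", "sex", "tiv", "diagnosis"]],
                           on="subject_id")
    abnorm = np.stack([trajs[s][k] for s, k in zip(v.true_subtype, v.true_stage)])
    vol = _volumes(config, es, abnorm, v.age, v.sex, v.tiv, v.scanner, rng, config.noise_sd)
    patients = pd.DataFrame({
        "subject_id": v.subject_id, "visit_index": v.visit_index, "group": "patient",
        "diagnosis": v.diagnosis, "age": v.age, "sex": v.sex, "tiv": v.tiv,
        "scanner": v.scanner, "scan_year": v.scan_year,
    })
    for j, r in enumerate(config.roi_names):
        patients[r] = vol[:, j]

    m = config.n_controls
    age = np.round(rng.normal(61.7, 11.1, m).clip(35, 92), 1)
    sex = np.where(rng.uniform(size=m) < 65 / 121, "F", "M")
    tiv = np.round(rng.normal(1.45e6, 1.3e5, m).clip(1.0e6, 1.9e6), 0)
    scanner = rng.choice(SCANNERS, size=m, p=_SCANNER_P)
    year = rng.integers(1998, 2020, m).astype(float)
    vol_c = _volumes(config, es, np.zeros((m, es.n_biomarkers)), age, sex, tiv, scanner, rng, 1.0)
    controls = pd.DataFrame({
        "subject_id": [f"C{i:04d}" for i in range(m)], "visit_index": 0,
        "group": "control", "diagnosis": "control", "age": age, "sex": sex,
        "tiv": tiv, "scanner": scanner, "scan_year": year,
    })
    for j, r in enumerate(config.roi_names):
        controls[r] = vol_c[:, j]
    return pd.concat([patients, controls], ignore_index=True)


def generate_followups(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Add follow-up visits to ``truth`` (in place) and return their volume rows.

    A fixed fraction of patients receives follow-ups; the interval is drawn
    from the configured mean/SD truncated at > 0, the true stage advances by
    round(stage_rate x interval) capped at N_events, and the scanner may
    change category with the configured probability.
    """
    es = truth.event_set
    rng = _rng(config, 3)
    n = len(truth.subjects)
    n_fu = int(round(n * config.followup_fraction))
    chosen = rng.choice(n, size=n_fu, replace=False)
    chosen = truth.subjects.subject_id.iloc[np.sort(chosen)].tolist()
    mean, sd = config.followup_interval_mean_sd

    rows = []
    base = truth.visits.set_index("subject_id")
    for sid in chosen:
        sub = truth.subjects[truth.subjects.subject_id == sid].iloc[0]
        prev = base.loc[sid]
        stage, age, scanner, year = (int(prev.true_stage), float(prev.age),
                                     str(prev.scanner), float(prev.scan_year))
        for visit in range(1, config.n_followup_visits + 1):
            interval = rng.normal(mean, sd)
            for _ in range(100):
                if interval > 0:
                    break
                interval = rng.normal(mean, sd)
            interval = float(abs(interval)) if interval <= 0 else float(interval)
            stage = min(stage + int(round(config.stage_rate * interval)), es.n_events)
            age = round(age + interval, 1)
            year += interval
            if rng.uniform() < config.scanner_change_prob:
                scanner = str(rng.choice([s for s in SCANNERS if s != scanner]))
            rows.append({"subject_id": sid, "visit_index": visit, "true_stage": stage,
                         "age": age, "scanner": scanner, "scan_year": year,
                         "interval": interval})
    fu = pd.DataFrame(rows)
    truth.visits = pd.concat([truth.visits, fu], ignore_index=True)

    v = fu.merge(truth.subjects[["subject_id", "true_subtype", "sex", "tiv", "diagnosis"]],
                 on="subject_id")
    trajs = {c + 1: trajectory_matrix(es, truth.sequences[c]) for c in range(len(truth.sequences))}
    abnorm = np.stack([trajs[s][k] for s, k in zip(v.true_subtype, v.true_stage)])
    vol = _volumes(config, es, abnorm, v.age, v.sex, v.tiv, v.scanner, rng, config.noise_sd)
    out = pd.DataFrame({
        "subject_id": v.subject_id, "visit_index": v.visit_index, "group": "patient",
        "diagnosis": v.diagnosis, "age": v.age, "sex": v.sex, "tiv": v.tiv,
        "scanner": v.scanner, "scan_year": v.scan_year,
    })
    for j, r in enumerate(config.roi_names):
        out[r] = vol[:, j]
    return out


def true_covariate_model(config: SyntheticConfig):
    """The generative covariate regression as a :class:`CovariateModel`.

    This is the infinite-control limit of ``fit_control_model`` on generated
    controls: exact coefficients and residual SD.  Scoring noise-free
    subjects with it recovers the planted abnormality exactly, which makes
    round-trip properties testable without control-sampling error.
    """
    import pandas as pd

    from .wscore import CovariateModel

    eff = config.covariate_effects
    b0 = np.array([ROI_BASELINE_MM3.get(r, 8000.0) for r in config.roi_names])
    sigma_roi = config.sigma_roi_fraction * b0
    sex_levels = ["F", "M"]
    scan_levels = sorted(SCANNERS)
    ref_off = eff.scanner.get(scan_levels[0], 0.0)
    terms = ["intercept", "sex[M]", "age", "tiv"] + [f"scanner[{s}]" for s in scan_levels[1:]]
    rows = [b0 + ref_off, np.full_like(b0, eff.sex_male), np.full_like(b0, eff.age),
            np.full_like(b0, eff.tiv)]
    rows += [np.full_like(b0, eff.scanner.get(s, 0.0) - ref_off) for s in scan_levels[1:]]
    coef = pd.DataFrame(np.vstack(rows), index=terms, columns=list(config.roi_names))
    return CovariateModel(("sex", "age", "tiv", "scanner"), tuple(config.roi_names), coef,
                          pd.Series(sigma_roi, index=list(config.roi_names)),
                          {"sex": sex_levels, "scanner": scan_levels}, control_n=0)


def generate_dataset(config: SyntheticConfig, followups: bool = True):
    """Full synthetic dataset: (volume table incl. follow-ups, truth)."""
    truth = generate_truth(config)
    baseline = generate_cohort(truth, config)
    if followups and config.followup_fraction > 0 and config.n_followup_visits > 0:
        fu = generate_followups(truth, config)
        table = pd.concat([baseline, fu], ignore_index=True)
    else:
        table = baseline
    return table, truth
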