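"""End-to-end analysis pipeline: data -> w-scores -> model -> reports.

Stages mirror the analysis order of a subtype-and-stage study: obtain a
cohort (synthetic or from files), fit the control covariate regression and
w-score all patient visits, optionally select the number of subtypes by
cross-validation, fit the subtype model on baseline visits and sample its
posterior by MCMC, assign every visit a subtype and stage, export positional
variance and pairwise subtype similarity with a randomized reference, and
produce longitudinal-stability and subtype-phenotype reports.  A JSON
manifest records the configuration, all seeds and the artifact names so a
run is fully reproducible from the manifest alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .events import ConfigurationError, build_event_set
from .longitudinal import EmptyLongitudinalData, stability_metrics
from .model import FitConfig, cross_validate, fit, mcmc
from .reports import contingency
from .similarity import model_distance, positional_variance, randomized_reference
from .staging import assign_table
from .synthetic import SyntheticConfig, generate_dataset
from .wscore import compute_wscores, fit_control_model

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "filter_rows"]

log = logging.getLogger("ppa_subtypes")

#: exit-code classes for the CLI
CONFIG_ERROR, DATA_ERROR, NUMERIC_ERROR = 2, 3, 4


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.code = code
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full run (serializable to/from YAML)."""

    output_dir: str = "ppa_subtypes_run"
    synthetic: bool = True
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_table: str | None = None  # CSV with patient and control rows
    thresholds: tuple = (1.0, 2.0, 3.0)
    n_subtypes: int | None = None  # fixed C; None -> cross-validated selection
    candidate_subtypes: tuple = (1, 2, 3, 4, 5)
    cv_folds: int = 10
    mcmc_iters: int = 10_000
    reference_pairs: int = 2000
    fit_restarts: int = 25
    fit_split_attempts: int = 5
    fit_split_restarts: int = 3
    seed: int = 0
    assignment_mode: str = "marginal"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic_config", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if syn:
            cfg.synthetic_config = SyntheticConfig(**syn)
        return cfg

    def fit_config(self) -> FitConfig:
        return FitConfig(n_restarts=self.fit_restarts,
                         n_split_attempts=self.fit_split_attempts,
                         n_split_restarts=self.fit_split_restarts,
                         seed=self.seed)


def filter_rows(table: pd.DataFrame, predicate: str) -> pd.DataFrame:
    """Row subset of a table by a pandas query string or a named predicate.

    Named predicates: ``same_scanner_followups`` keeps baseline rows plus
    follow-up rows acquired on the subject's baseline scanner (the
    same-scanner longitudinal sensitivity subset).  Any other string is
    evaluated as a ``DataFrame.query`` expression; unknown columns raise.
    """
    if predicate == "same_scanner_followups":
        baseline = table[table.visit_index == 0]
        base_scanner = baseline.set_index("subject_id").scanner
        keep = (table.visit_index == 0) | (
            table.scanner == table.subject_id.map(base_scanner))
        out = table[keep]
    else:
        try:
            out = table.query(predicate)
        except Exception as exc:  # noqa: BLE001 - surface as config error
            raise ConfigurationError(f"bad row predicate {predicate!r}: {exc}") from exc
    log.info("filter %r: %d of %d rows retained", predicate, len(out), len(table))
    return out


def _stage(name: str, code: int, func, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = func(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, code, exc) from exc
    log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {"config": _config_dict(config), "artifacts": {}, "seeds": {
        "pipeline": config.seed, "synthetic": config.synthetic_config.seed,
        "mcmc": config.seed + 1, "reference": config.seed + 2, "cv": config.seed + 3},
        "versions": {"ppa_subtypes": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__}}

    def art(name, filename):
        manifest["artifacts"][name] = filename
        return out / filename

    # --- data
    if config.synthetic:
        table, truth = _stage("simulate", DATA_ERROR, generate_dataset, config.synthetic_config)
        io.write_table(table, art("cohort", "cohort.csv"))
        io.write_table(truth.subjects, art("truth_subjects", "truth_subjects.csv"))
        io.write_table(truth.visits, art("truth_visits", "truth_visits.csv"))
    elif config.input_table:
        table = _stage("load", DATA_ERROR, io.read_table, config.input_table)
    else:
        raise PipelineError("load", CONFIG_ERROR,
                            ConfigurationError("neither synthetic mode nor input_table given"))

    rois = [c for c in table.columns if c not in
            ("subject_id", "visit_index", "group", "diagnosis", "age", "sex",
             "tiv", "scanner", "scan_year")]
    event_set = build_event_set(rois, config.thresholds)
    manifest["n_events"] = event_set.n_events

    # --- w-scoring
    controls = table[table.group == "control"]
    patients = table[table.group == "patient"]
    cov_model = _stage("wscore", DATA_ERROR, fit_control_model, controls)
    io.save_covariate_model(cov_model, art("covariate_model", "covariate_model.yaml"))
    W_all = _stage("wscore", DATA_ERROR, compute_wscores, patients, cov_model)
    io.write_wscores(W_all, art("wscores", "wscores.csv"))
    baseline_mask = patients.visit_index.to_numpy() == 0
    W_base = W_all[baseline_mask]

    fit_cfg = config.fit_config()

    # --- model selection
    if config.n_subtypes is None:
        cv = _stage("select", NUMERIC_ERROR, cross_validate, W_base, event_set,
                    config.candidate_subtypes, config.cv_folds,
                    config=fit_cfg, seed=config.seed + 3)
        io.dump_yaml(cv.as_dict(), out / "cvic.yaml")
        manifest["artifacts"]["cvic"] = "cvic.yaml"
        n_subtypes = cv.selected
    else:
        n_subtypes = config.n_subtypes
    manifest["n_subtypes"] = int(n_subtypes)

    # --- fit + MCMC
    model = _stage("fit", NUMERIC_ERROR, fit, W_base, event_set, n_subtypes, config=fit_cfg)
    model = _stage("mcmc", NUMERIC_ERROR, mcmc, W_base, model, config.mcmc_iters,
                   config.seed + 1)
    io.save_model(model, art("model", "model.yaml"), art("mcmc_samples", "mcmc_samples.csv"))

    # --- assignment
    assignments = _stage("assign", NUMERIC_ERROR, assign_table, W_all, model,
                         config.assignment_mode)
    meta = patients[["subject_id", "visit_index", "diagnosis"]]
    assignments = assignments.merge(meta, on=["subject_id", "visit_index"], how="left")
    io.write_table(assignments, art("assignments", "assignments.csv"))

    # --- similarity
    pvds = [positional_variance(s) for s in model.mcmc_samples]
    for c, P in enumerate(pvds):
        df = pd.DataFrame(P, index=list(model.event_set.labels),
                          columns=[f"stage{k + 1}" for k in range(event_set.n_events)])
        df.to_csv(art(f"pvd_subtype_{c + 1}", f"pvd_subtype_{c + 1}.csv"))
    dist = {f"S{a + 1}-S{b + 1}": model_distance(pvds[a], pvds[b])
            for a in range(len(pvds)) for b in range(a + 1, len(pvds))}
    ref = _stage("similarity", NUMERIC_ERROR, randomized_reference, event_set,
                 "delta-permutation", config.reference_pairs, config.seed + 2)
    io.dump_yaml({"pairwise_distance": dist, "randomized_reference": ref.as_dict()},
                 out / "similarity.yaml")
    manifest["artifacts"]["similarity"] = "similarity.yaml"

    # --- longitudinal
    try:
        report = _stage("longitudinal", DATA_ERROR, stability_metrics, assignments)
        io.dump_yaml(report.as_dict(), out / "stability.yaml")
        report.transition_matrix.to_csv(art("transitions", "transitions.csv"))
        manifest["artifacts"]["stability"] = "stability.yaml"
    except PipelineError as exc:
        if not isinstance(exc.cause, EmptyLongitudinalData):
            raise
        log.info("no longitudinal visits; skipping stability report")

    # --- phenotype report
    base_assign = assignments[assignments.visit_index == 0]
    try:
        rep = _stage("report", DATA_ERROR, contingency, base_assign)
        io.dump_yaml(rep.as_dict(), out / "contingency.yaml")
        manifest["artifacts"]["contingency"] = "contingency.yaml"
    except PipelineError as exc:
        if not isinstance(exc.cause, (ConfigurationError, KeyError, AttributeError)):
            raise
        log.info("no usable diagnosis labels; skipping contingency report")

    io.write_manifest(manifest, out / "manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    syn = d["synthetic_config"]
    for k, v in list(syn.items()):
        if isinstance(v, np.ndarray):
            syn[k] = v.tolist()
    return d
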