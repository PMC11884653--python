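"""Reading and writing of pipeline artifacts.

Everything is delimited text or structured text: volume tables, w-score
matrices, MCMC samples and positional-variance matrices as CSV; covariate
and subtype models as YAML with full coefficient/sequence provenance; run
manifests as JSON with sorted keys so identical runs serialize identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import EventSet, build_event_set
from .model import SubtypeModel
from .wscore import CovariateModel

__all__ = [
    "read_table", "write_table", "write_wscores", "read_wscores",
    "save_covariate_model", "load_covariate_model",
    "save_model", "load_model", "write_manifest",
]


def read_table(path) -> pd.DataFrame:
    """Read a regional volume table (CSV, one row per visit)."""
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_wscores(W: pd.DataFrame, path) -> None:
    W.to_csv(path, index=True)


def read_wscores(path) -> pd.DataFrame:
    W = pd.read_csv(path, index_col=[0, 1])
    return W


def save_covariate_model(model: CovariateModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=True))


def load_covariate_model(path) -> CovariateModel:
    return CovariateModel.from_dict(yaml.safe_load(Path(path).read_text()))


def _event_set_dict(es: EventSet) -> dict:
    # thresholds are shared across biomarkers in every supported configuration
    thr = sorted(set(float(z) for z in es.event_threshold))
    return {"roi_names": list(es.biomarker_names), "thresholds": thr,
            "z_max_offset": float(es.z_max[0] - max(thr))}


def save_model(model: SubtypeModel, path, samples_path=None) -> None:
    """Serialize a fitted model; MCMC samples go to a sidecar CSV if given."""
    d = {
        "event_set": _event_set_dict(model.event_set),
        "n_subtypes": int(model.n_subtypes),
        "sequences": [[model.event_set.labels[e] for e in seq] for seq in model.sequences],
        "sequence_ids": [[int(e) for e in seq] for seq in model.sequences],
        "fractions": [float(f) for f in model.fractions],
        "sigma": [float(s) for s in model.sigma],
        "log_likelihood": float(model.log_likelihood),
        "fit_log": _jsonable(model.fit_log),
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
    if samples_path is not None and model.mcmc_samples is not None:
        frames = []
        for c, s in enumerate(model.mcmc_samples):
            df = pd.DataFrame(s, columns=[f"pos{j}" for j in range(s.shape[1])])
            df.insert(0, "subtype", c + 1)
            df.insert(1, "iteration", np.arange(s.shape[0]))
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(samples_path, index=False)


def load_model(path, samples_path=None) -> SubtypeModel:
    d = yaml.safe_load(Path(path).read_text())
    es = build_event_set(d["event_set"]["roi_names"], d["event_set"]["thresholds"],
                         d["event_set"]["z_max_offset"])
    model = SubtypeModel(
        event_set=es,
        sequences=np.asarray(d["sequence_ids"], dtype=np.int64),
        fractions=np.asarray(d["fractions"], dtype=float),
        sigma=np.asarray(d["sigma"], dtype=float),
        log_likelihood=float(d["log_likelihood"]),
        fit_log=d.get("fit_log", {}),
    )
    if samples_path is not None and Path(samples_path).exists():
        df = pd.read_csv(samples_path)
        samples = []
        for c in range(model.n_subtypes):
            sub = df[df.subtype == c + 1].sort_values("iteration")
            samples.append(sub[[f"pos{j}" for j in range(es.n_events)]].to_numpy(np.int16))
        model.mcmc_samples = samples
    return model


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")


def dump_yaml(obj, path) -> None:
    """YAML-serialize after coercing numpy scalars/arrays to plain Python."""
    Path(path).write_text(yaml.safe_dump(_jsonable(obj), sort_keys=True))
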