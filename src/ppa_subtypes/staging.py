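"""Per-visit subtype and stage assignment from a trained model.

The joint posterior over (subtype c, stage k) of a w-score row x is

    P(c, k | x) ∝ f_c * L(x | S_c, k) / (N_events + 1),

computed in log space.  The assigned stage maximizes the subtype-marginal
stage posterior; individuals at stage zero are deemed not *subtypable*
(their volumes are comparable to controls) and receive no subtype; everyone
else is assigned their most probable subtype under the stage-marginal
subtype posterior.  A joint-argmax mode is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import ConfigurationError
from .model import SubtypeModel, stage_loglik_matrix, _as_matrix
from .wscore import CovariateModel, compute_wscores, fit_control_model

__all__ = ["joint_log_posterior", "posterior", "assign", "assign_table", "assign_external"]


def joint_log_posterior(W, model: SubtypeModel) -> np.ndarray:
    """Normalized log P(c, k | x) for every row; shape (n, C, N+1)."""
    W = _as_matrix(W)
    trajs = model.trajectories()
    logp = np.stack(
        [stage_loglik_matrix(W, trajs[c], model.sigma) for c in range(model.n_subtypes)],
        axis=1,
    )
    logp += np.log(model.fractions)[None, :, None] - np.log(model.n_events + 1.0)
    flat = logp.reshape(W.shape[0], -1)
    m = flat.max(axis=1, keepdims=True)
    logz = m + np.log(np.exp(flat - m).sum(axis=1, keepdims=True))
    return logp - logz[:, :, None]


def posterior(w_row, model: SubtypeModel) -> dict:
    """Posterior summaries for one w-score row.

    Returns the joint (C, N+1) posterior plus its stage marginal (over
    subtypes) and subtype marginal (over stages).
    """
    lp = joint_log_posterior(np.atleast_2d(np.asarray(w_row, dtype=float)), model)[0]
    joint = np.exp(lp)
    return {
        "joint": joint,
        "stage_posterior": joint.sum(axis=0),
        "subtype_posterior": joint.sum(axis=1),
    }


def assign(w_row, model: SubtypeModel, mode: str = "marginal") -> dict:
    """Assign one row; see :func:`assign_table` for the vectorized form."""
    rec = assign_table(pd.DataFrame(np.atleast_2d(np.asarray(w_row, dtype=float)),
                                    index=pd.MultiIndex.from_tuples([("", 0)],
                                                                    names=["subject_id", "visit_index"]),
                                    columns=model.event_set.biomarker_names),
                       model, mode=mode)
    return rec.iloc[0].to_dict()


def assign_table(W: pd.DataFrame, model: SubtypeModel, mode: str = "marginal") -> pd.DataFrame:
    """Subtype/stage assignment records for every row of a w-score matrix.

    ``mode='marginal'`` (default): stage = argmax of the stage posterior
    marginalized over subtypes; subtype = argmax of the subtype posterior
    marginalized over stages.  ``mode='joint'``: both from the joint argmax.
    Rows assigned stage 0 are flagged unsubtypable with no subtype.  Subtype
    labels are 1-based; companion columns carry the full posterior vectors.
    """
    if mode not in ("marginal", "joint"):
        raise ConfigurationError(f"unknown assignment mode {mode!r}")
    lp = joint_log_posterior(W, model)
    joint = np.exp(lp)
    stage_post = joint.sum(axis=1)  # (n, N+1)
    subtype_post = joint.sum(axis=2)  # (n, C)

    if mode == "marginal":
        stage = stage_post.argmax(axis=1)
        subtype = subtype_post.argmax(axis=1) + 1
    else:
        flat = joint.reshape(joint.shape[0], -1).argmax(axis=1)
        subtype = flat // (model.n_events + 1) + 1
        stage = flat % (model.n_events + 1)

    subtypable = stage > 0
    prob = subtype_post[np.arange(len(subtype)), subtype - 1]

    if isinstance(W, pd.DataFrame) and isinstance(W.index, pd.MultiIndex):
        sid = W.index.get_level_values(0)
        vis = W.index.get_level_values(1)
    else:
        sid = [f"row{i}" for i in range(stage.shape[0])]
        vis = np.zeros(stage.shape[0], dtype=int)

    out = pd.DataFrame({
        "subject_id": sid, "visit_index": vis,
        "stage": stage.astype(int),
        "subtype": pd.array(np.where(subtypable, subtype, 0), dtype="Int64"),
        "subtypable": subtypable,
        "assignment_probability": np.where(subtypable, prob, np.nan),
    })
    out.loc[~out.subtypable, "subtype"] = pd.NA
    for c in range(model.n_subtypes):
        out[f"p_subtype_{c + 1}"] = subtype_post[:, c]
    for k in range(model.n_events + 1):
        out[f"p_stage_{k}"] = stage_post[:, k]
    return out


def assign_external(table: pd.DataFrame, own_controls: pd.DataFrame, model: SubtypeModel,
                    covariates=None, mode: str = "marginal") -> pd.DataFrame:
    """Assign an independently collected cohort with an already-trained model.

    The external cohort is w-scored against *its own* controls (a fresh
    covariate regression); the trained subtype model is then applied without
    refitting.  The external ROI set must match the model's event set.
    """
    from .wscore import DEFAULT_COVARIATES, roi_columns

    rois = tuple(model.event_set.biomarker_names)
    missing = [r for r in rois if r not in table.columns]
    if missing or not set(rois) <= set(own_controls.columns):
        raise ConfigurationError(
            f"external ROI set does not match the model's event set (missing {missing})")
    cov_model = fit_control_model(own_controls, covariates or DEFAULT_COVARIATES, rois=rois)
    W = compute_wscores(table, cov_model)
    return assign_table(W, model, mode=mode)
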