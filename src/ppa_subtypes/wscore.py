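"""Covariate-adjusted w-scores of regional brain volumes.

The w-score (covariate-adjusted z-score) of a patient's regional volume is

    w = (observed - predicted) / residual SD,

where the prediction comes from an ordinary least-squares regression of the
control cohort's volumes on sex, age at scan, total intracranial volume and
scanner type, and the residual SD is the degrees-of-freedom-corrected
standard deviation of the control residuals.  Because atrophy *lowers*
volume, the score is negated by default so that larger values mean more
abnormal, matching the ascending severity thresholds (1, 2, 3) of the event
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CovariateModel", "fit_control_model", "compute_wscores", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ("sex", "age", "tiv", "scanner")

#: columns of a regional volume table that are not ROI volumes
TABLE_COLUMNS = ("subject_id", "visit_index", "group", "diagnosis",
                 "age", "sex", "tiv", "scanner", "scan_year")


class WScoreError(ValueError):
    """Invalid input to the w-scoring regression."""


@dataclass
class CovariateModel:
    """Per-ROI control regression: coefficients, residual SD and encoding.

    ``coefficients`` has one row per design term (intercept first, then the
    covariates in configured order, categoricals expanded against a reference
    level) and one column per ROI.  ``categories`` records the levels seen in
    the controls for every categorical covariate; scoring a row with an
    unseen level is an explicit error, never a silent extrapolation.
    """

    covariates: tuple[str, ...]
    roi_names: tuple[str, ...]
    coefficients: pd.DataFrame  # terms x ROIs
    residual_sd: pd.Series  # per ROI, > 0
    categories: dict[str, list]
    control_n: int

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "roi_names": list(self.roi_names),
            "terms": list(self.coefficients.index),
            "coefficients": {r: [float(x) for x in self.coefficients[r]] for r in self.roi_names},
            "residual_sd": {r: float(self.residual_sd[r]) for r in self.roi_names},
            "categories": {k: list(v) for k, v in self.categories.items()},
            "control_n": int(self.control_n),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateModel":
        coef = pd.DataFrame({r: d["coefficients"][r] for r in d["roi_names"]}, index=d["terms"])
        return cls(tuple(d["covariates"]), tuple(d["roi_names"]), coef,
                   pd.Series(d["residual_sd"]), {k: list(v) for k, v in d["categories"].items()},
                   int(d["control_n"]))


def roi_columns(table: pd.DataFrame) -> list[str]:
    """ROI volume columns of a regional volume table (non-metadata columns)."""
    return [c for c in table.columns if c not in TABLE_COLUMNS]


def _is_categorical(series: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(series)


def _design_matrix(table: pd.DataFrame, covariates, categories: dict[str, list] | None):
    """Intercept + covariates, categoricals dummy-coded against a reference.

    When ``categories`` is given (scoring with a fitted model) the stored
    levels are enforced; unseen levels raise.  When None (fitting), levels
    are taken from the data in sorted order, the first being the reference.
    """
    cols = [np.ones(len(table))]
    names = ["intercept"]
    fit_mode = categories is None
    cats: dict[str, list] = {} if fit_mode else categories
    for cov in covariates:
        if cov not in table.columns:
            raise WScoreError(f"covariate {cov!r} missing from table")
        s = table[cov]
        if s.isna().any():
            raise WScoreError(f"covariate {cov!r} has missing values (no silent imputation)")
        if _is_categorical(s):
            if fit_mode:
                cats[cov] = sorted(map(str, s.unique()))
            levels = cats[cov]
            unseen = sorted(set(map(str, s.unique())) - set(levels))
            if unseen:
                raise WScoreError(f"unseen {cov} categor{'ies' if len(unseen) > 1 else 'y'} {unseen}; "
                                  f"model knows {levels}")
            for lev in levels[1:]:  # first level is the reference
                cols.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(s.to_numpy(float))
            names.append(cov)
    return np.column_stack(cols), names, cats


def fit_control_model(controls: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                      rois=None) -> CovariateModel:
    """OLS fit of every ROI volume on the covariates, over control rows.

    Controls must be one (baseline) row per subject.  Residual SD per ROI is
    sqrt(SSR / (n - p)), guarded away from zero, so in-sample w-scores have
    unit scale under that same degrees-of-freedom convention.
    """
    rois = list(rois) if rois is not None else roi_columns(controls)
    if controls["subject_id"].duplicated().any():
        raise WScoreError("controls must have exactly one baseline row per subject")
    X, names, cats = _design_matrix(controls, covariates, None)
    n, p = X.shape
    if n < p + 2:
        raise WScoreError(f"need at least {p + 2} control rows for {p} parameters, got {n}")
    Y = controls[rois].to_numpy(float)
    if np.any(Y <= 0) or np.any(controls["tiv"].to_numpy(float) <= 0):
        raise WScoreError("volumes and TIV must be strictly positive")
    if np.linalg.matrix_rank(X) < p:
        raise WScoreError("rank-deficient design: covariates are collinear")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = np.sqrt((resid**2).sum(axis=0) / (n - p))
    sd = np.maximum(sd, 1e-8)  # epsilon guard for degenerate (noise-free) fits
    coef = pd.DataFrame(beta, index=names, columns=rois)
    return CovariateModel(tuple(covariates), tuple(rois), coef,
                          pd.Series(sd, index=rois), cats, n)


def compute_wscores(rows: pd.DataFrame, model: CovariateModel, sign_flip: bool = True) -> pd.DataFrame:
    """Signed abnormality scores for every row, indexed by (subject, visit).

    raw = (observed - predicted) / residual SD; with ``sign_flip`` (default)
    the output is -raw, so atrophy (volume loss) is positive and grows with
    severity.
    """
    X, _, _ = _design_matrix(rows, model.covariates, model.categories)
    missing = [r for r in model.roi_names if r not in rows.columns]
    if missing:
        raise WScoreError(f"table lacks ROI columns {missing}")
    Y = rows[list(model.roi_names)].to_numpy(float)
    raw = (Y - X @ model.coefficients.to_numpy()) / model.residual_sd.to_numpy()
    if sign_flip:
        raw = -raw
    idx = pd.MultiIndex.from_frame(rows[["subject_id", "visit_index"]])
    W = pd.DataFrame(raw, index=idx, columns=model.roi_names)
    W.attrs["sign_flip"] = sign_flip
    W.attrs["control_n"] = model.control_n
    return W
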