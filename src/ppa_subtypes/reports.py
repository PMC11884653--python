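"""Subtype-phenotype cross-tabulation and single-phenotype staging.

The association between data-driven subtypes and clinical diagnoses is
summarized by a subtype x diagnosis count table with a Pearson chi-square
contingency test (no continuity correction).  For comparing a clinical
phenotype's progression pattern with the discovered subtypes, a
single-sequence model (one subtype) is fitted to the phenotype's subjects
with all other parameters unchanged; its positional variance can then be
compared with each discovered subtype's by Hellinger distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import ConfigurationError, EventSet
from .model import FitConfig, SubtypeModel, fit

__all__ = ["ContingencyReport", "contingency", "single_phenotype_fit"]


@dataclass
class ContingencyReport:
    table: pd.DataFrame  # subtype x diagnosis counts
    chi2: float
    dof: int
    n: int
    p_value: float

    def as_dict(self) -> dict:
        return {"table": {str(i): {str(c): int(v) for c, v in row.items()}
                          for i, row in self.table.iterrows()},
                "chi2": float(self.chi2), "dof": int(self.dof),
                "n": int(self.n), "p_value": float(self.p_value)}


def contingency(assignments: pd.DataFrame, diagnoses: pd.Series | None = None) -> ContingencyReport:
    """Chi-square contingency test of subtype vs clinical diagnosis.

    Uses subtypable baseline visits only.  ``diagnoses`` maps subject_id to
    diagnosis label; alternatively the assignments frame may already carry a
    ``diagnosis`` column.  Zero-margin rows/columns are dropped with a
    warning before testing.
    """
    a = assignments[assignments.subtypable].copy()
    if diagnoses is not None:
        a["diagnosis"] = a.subject_id.map(diagnoses)
    if "diagnosis" not in a.columns:
        raise ConfigurationError("no diagnosis labels supplied")
    a = a.dropna(subset=["diagnosis"])
    table = pd.crosstab(a.subtype.astype(int), a.diagnosis, dropna=False)
    table.index = [f"S{c}" for c in table.index]

    empty_rows = table.index[(table.sum(axis=1) == 0)]
    empty_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(f"dropping zero-margin rows {list(empty_rows)} / columns {list(empty_cols)}")
        table = table.drop(index=empty_rows, columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ConfigurationError("contingency test needs at least a 2x2 table with nonzero margins")

    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ContingencyReport(table, float(chi2), int(dof), int(table.to_numpy().sum()), float(p))


def single_phenotype_fit(W: pd.DataFrame, diagnosis_labels: pd.Series, phenotype: str,
                         event_set: EventSet, *, sigma=None, config: FitConfig | None = None,
                         min_subjects: int = 20) -> SubtypeModel:
    """One-subtype staging model for a single clinical phenotype.

    Restricts the w-score matrix to baseline rows whose subject carries the
    given diagnosis and fits a single-sequence model through exactly the same
    code path as the full subtype fit.
    """
    sid = W.index.get_level_values(0) if isinstance(W.index, pd.MultiIndex) else W.index
    labels = pd.Series(sid).map(diagnosis_labels).to_numpy()
    mask = labels == phenotype
    n = int(mask.sum())
    if n < min_subjects:
        raise ConfigurationError(
            f"only {n} subjects with diagnosis {phenotype!r}; need >= {min_subjects}")
    return fit(W[mask], event_set, 1, sigma=sigma, config=config)
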