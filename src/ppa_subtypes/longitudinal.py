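"""Longitudinal consistency of subtype and stage assignments.

Given per-visit assignment records, quantifies how stable the model's
subtype labels are between baseline and first follow-up, how stages evolve
(advanced / same / regressed), and the full baseline-to-follow-up subtype
transition matrix.  Subjects unsubtypable at baseline are excluded from the
stability denominators, and staging consistency is computed among
stable-subtype subjects only; follow-up visits that fall to stage zero are
counted in a separate sink column of the transition matrix and excluded
from the stability denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StabilityReport", "stability_metrics", "transition_counts"]


class EmptyLongitudinalData(ValueError):
    """No subject has more than one visit."""


@dataclass
class StabilityReport:
    """Counts and fractions describing assignment stability across visits."""

    n_longitudinal: int  # subjects with >= 2 visits, subtypable at baseline
    n_usable: int  # of those, with a subtypable first follow-up
    per_subtype_stability: dict  # baseline subtype -> fraction stable
    overall_stability: float
    n_stable: int
    stage_advanced: int
    stage_same: int
    stage_regressed: int
    staging_consistency: float  # same-or-advanced among stable-subtype subjects
    staging_consistency_all_pairs: float  # same-or-advanced among all usable pairs
    mean_stable_assignment_probability: float
    multi_visit_always_same_subtype: int
    multi_visit_monotone_stage: int
    n_multi_visit: int
    transition_matrix: pd.DataFrame = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "n_longitudinal": self.n_longitudinal,
            "n_usable": self.n_usable,
            "per_subtype_stability": {str(k): float(v) for k, v in self.per_subtype_stability.items()},
            "overall_stability": float(self.overall_stability),
            "n_stable": self.n_stable,
            "stage_outcomes": {"advanced": self.stage_advanced, "same": self.stage_same,
                               "regressed": self.stage_regressed},
            "staging_consistency": float(self.staging_consistency),
            "staging_consistency_all_pairs": float(self.staging_consistency_all_pairs),
            "mean_stable_assignment_probability": float(self.mean_stable_assignment_probability),
            "multi_visit": {"n": self.n_multi_visit,
                            "always_same_subtype": self.multi_visit_always_same_subtype,
                            "monotone_stage": self.multi_visit_monotone_stage},
        }


def _pairs(assignments: pd.DataFrame) -> pd.DataFrame:
    """Baseline / first-follow-up pairs per subject, sorted by visit index."""
    a = assignments.sort_values(["subject_id", "visit_index"])
    rows = []
    for sid, g in a.groupby("subject_id", sort=True):
        if len(g) < 2:
            continue
        b, f = g.iloc[0], g.iloc[1]
        rows.append({"subject_id": sid,
                     "baseline_subtype": b.subtype, "baseline_stage": b.stage,
                     "baseline_subtypable": bool(b.subtypable),
                     "baseline_probability": b.assignment_probability,
                     "followup_subtype": f.subtype, "followup_stage": f.stage,
                     "followup_subtypable": bool(f.subtypable)})
    return pd.DataFrame(rows)


def stability_metrics(assignments: pd.DataFrame) -> StabilityReport:
    """Stability fractions and stage outcomes between baseline and follow-up.

    ``assignments`` is the output of :func:`ppa_subtypes.staging.assign_table`
    covering several visits per subject.  Metrics are invariant to row order
    (visits are sorted internally).
    """
    pairs = _pairs(assignments)
    if pairs.empty:
        raise EmptyLongitudinalData("no subject has two or more visits")
    pairs = pairs[pairs.baseline_subtypable]
    n_longitudinal = len(pairs)
    usable = pairs[pairs.followup_subtypable]
    n_usable = len(usable)

    stable_mask = usable.baseline_subtype == usable.followup_subtype
    stable = usable[stable_mask]
    per_subtype = {}
    for c, g in usable.groupby("baseline_subtype", sort=True):
        per_subtype[int(c)] = float((g.baseline_subtype == g.followup_subtype).mean())
    overall = float(stable_mask.mean()) if n_usable else float("nan")

    diff = stable.followup_stage - stable.baseline_stage
    advanced = int((diff > 0).sum())
    same = int((diff == 0).sum())
    regressed = int((diff < 0).sum())
    consistency = float((advanced + same) / len(stable)) if len(stable) else float("nan")
    # alternative denominator: every usable pair, whether or not the subtype held
    diff_all = usable.followup_stage - usable.baseline_stage
    consistency_all = float((diff_all >= 0).mean()) if n_usable else float("nan")
    mean_prob = float(stable.baseline_probability.mean()) if len(stable) else float("nan")

    # multi-visit summaries over all visits of subjects with >= 2 visits
    a = assignments.sort_values(["subject_id", "visit_index"])
    always_same = monotone = n_multi = 0
    for sid, g in a.groupby("subject_id", sort=True):
        if len(g) < 2 or not bool(g.iloc[0].subtypable):
            continue
        n_multi += 1
        subs = g.subtype.dropna().unique()
        if len(subs) == 1 and g.subtype.notna().all():
            always_same += 1
        if np.all(np.diff(g.stage.to_numpy()) >= 0):
            monotone += 1

    return StabilityReport(
        n_longitudinal=n_longitudinal, n_usable=n_usable,
        per_subtype_stability=per_subtype, overall_stability=overall,
        n_stable=len(stable), stage_advanced=advanced, stage_same=same,
        stage_regressed=regressed, staging_consistency=consistency,
        staging_consistency_all_pairs=consistency_all,
        mean_stable_assignment_probability=mean_prob,
        multi_visit_always_same_subtype=always_same,
        multi_visit_monotone_stage=monotone, n_multi_visit=n_multi,
        transition_matrix=transition_counts(assignments),
    )


def transition_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Baseline-to-follow-up subtype transition counts (the Sankey data).

    Rows: baseline subtype; columns: follow-up subtype plus a ``stage_zero``
    sink for follow-ups that fall back to stage zero.  Only subjects
    subtypable at baseline with at least one follow-up are counted.
    """
    pairs = _pairs(assignments)
    if pairs.empty:
        raise EmptyLongitudinalData("no subject has two or more visits")
    pairs = pairs[pairs.baseline_subtypable]
    subtypes = sorted(assignments.subtype.dropna().unique().astype(int))
    cols = [f"S{c}" for c in subtypes] + ["stage_zero"]
    T = pd.DataFrame(0, index=[f"S{c}" for c in subtypes], columns=cols)
    for _, r in pairs.iterrows():
        row = f"S{int(r.baseline_subtype)}"
        col = "stage_zero" if not r.followup_subtypable else f"S{int(r.followup_subtype)}"
        T.loc[row, col] += 1
    return T
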