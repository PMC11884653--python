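"""Threshold events and piecewise-linear severity trajectories.

A model *event* is a (biomarker, w-score threshold) pair; "occurring" means the
biomarker's abnormality has reached that threshold.  A subtype is described by
a permutation of the full event set (its *sequence*); the stage of a subject
is a position along that sequence, 0 meaning no event has occurred.

The expected abnormality of biomarker ``b`` at stage ``k`` under a sequence is
a piecewise-linear trajectory anchored at 0 at stage 0, at each threshold
``z_r`` at the stage where event ``(b, z_r)`` sits in the sequence, and rising
toward a ceiling ``z_max`` at the final stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventSet", "build_event_set", "canonicalize_sequence", "trajectory_matrix", "expected_value"]


class ConfigurationError(ValueError):
    """Invalid model or generator configuration."""


@dataclass(frozen=True)
class EventSet:
    """The full set of (biomarker, threshold) events of a model.

    Events are enumerated biomarker-major with thresholds ascending, so with
    19 regions and shared thresholds (1, 2, 3) the event ids are
    ``0 = (roi0, 1), 1 = (roi0, 2), 2 = (roi0, 3), 3 = (roi1, 1), ...`` and
    ``n_events = 57``.
    """

    biomarker_names: tuple[str, ...]
    event_biomarker: np.ndarray  # (n_events,) int, biomarker index per event
    event_threshold: np.ndarray  # (n_events,) float, threshold per event
    z_max: np.ndarray  # (n_biomarkers,) trajectory ceiling per biomarker
    labels: tuple[str, ...] = field(default=())

    @property
    def n_events(self) -> int:
        return self.event_biomarker.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarker_names)

    def events_of(self, b: int) -> np.ndarray:
        """Event ids of biomarker ``b``, in ascending threshold order."""
        return np.flatnonzero(self.event_biomarker == b)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        return (
            self.biomarker_names == other.biomarker_names
            and np.array_equal(self.event_biomarker, other.event_biomarker)
            and np.array_equal(self.event_threshold, other.event_threshold)
            and np.array_equal(self.z_max, other.z_max)
        )


def build_event_set(
    roi_names,
    thresholds=(1.0, 2.0, 3.0),
    z_max_offset: float = 2.0,
) -> EventSet:
    """Enumerate the event set for ``roi_names`` with shared ``thresholds``.

    Parameters
    ----------
    roi_names : sequence of str
        Biomarker (region of interest) names.
    thresholds : sequence of float
        Strictly ascending positive w-score severity levels shared by all
        biomarkers; (1, 2, 3) for the primary configuration, (2, 4, 5) or
        (1, 3) for the sensitivity configurations.
    z_max_offset : float
        Ceiling above the top threshold toward which trajectories keep rising
        after the last event (z_max = max(thresholds) + z_max_offset).
    """
    roi_names = tuple(str(r) for r in roi_names)
    thr = np.asarray(thresholds, dtype=float)
    if len(roi_names) < 1:
        raise ConfigurationError("at least one ROI is required")
    if thr.size < 1:
        raise ConfigurationError("at least one threshold is required")
    if np.any(thr <= 0) or np.any(np.diff(thr) <= 0):
        raise ConfigurationError(f"thresholds must be strictly ascending and positive, got {thresholds}")
    B, R = len(roi_names), thr.size
    event_bio = np.repeat(np.arange(B), R)
    event_thr = np.tile(thr, B)
    z_max = np.full(B, thr[-1] + z_max_offset)
    labels = tuple(f"{roi_names[b]}:{_fmt(z)}" for b, z in zip(event_bio, event_thr))
    return EventSet(roi_names, event_bio, event_thr, z_max, labels)


def _fmt(z: float) -> str:
    return str(int(z)) if float(z).is_integer() else str(z)


def canonicalize_sequence(event_set: EventSet, order: np.ndarray) -> np.ndarray:
    """Re-sort each biomarker's events into ascending threshold order.

    ``order`` is a permutation of event ids.  The set of positions occupied by
    each biomarker's events is preserved; within those positions the events
    are reassigned so thresholds ascend (trajectories are monotone, so a
    descending threshold order is physically meaningless).
    """
    order = np.asarray(order)
    pos = np.empty(event_set.n_events, dtype=np.int64)
    pos[order] = np.arange(event_set.n_events)
    out = np.array(order)
    for b in range(event_set.n_biomarkers):
        ev = event_set.events_of(b)  # ascending threshold
        p = np.sort(pos[ev])
        out[p] = ev
    return out


def _check_permutation(event_set: EventSet, order: np.ndarray) -> np.ndarray:
    order = np.asarray(order)
    if order.shape != (event_set.n_events,) or not np.array_equal(np.sort(order), np.arange(event_set.n_events)):
        raise ConfigurationError("sequence must be a permutation of the full event set")
    return order


def trajectory_matrix(event_set: EventSet, order: np.ndarray) -> np.ndarray:
    """Expected abnormality for every (stage, biomarker) under a sequence.

    Returns an array ``E`` of shape ``(n_events + 1, n_biomarkers)`` with
    ``E[k, b]`` the expected w-score of biomarker ``b`` at stage ``k``:
    0 at stage 0, exactly ``z_r`` at the stage of event ``(b, z_r)``, linear
    in between, and rising linearly toward ``z_max[b]`` at the final stage
    (unless the last threshold event itself sits at the final stage).
    """
    order = np.asarray(order)
    N, B = event_set.n_events, event_set.n_biomarkers
    pos = np.empty(N, dtype=np.int64)
    pos[order] = np.arange(1, N + 1)  # event id -> stage at which it occurs
    stages = np.arange(N + 1, dtype=float)
    E = np.empty((N + 1, B))
    for b in range(B):
        ev = event_set.events_of(b)
        p = pos[ev].astype(float)
        if np.any(np.diff(p) <= 0):
            raise ConfigurationError("within-biomarker threshold events must appear in ascending order")
        xp = np.concatenate(([0.0], p))
        fp = np.concatenate(([0.0], event_set.event_threshold[ev]))
        if p[-1] < N:
            xp = np.append(xp, float(N))
            fp = np.append(fp, event_set.z_max[b])
        E[:, b] = np.interp(stages, xp, fp)
    return E


def expected_value(event_set: EventSet, order: np.ndarray, biomarker: int, stage: int) -> float:
    """Expected w-score of one biomarker at one stage under a sequence."""
    if not 0 <= stage <= event_set.n_events:
        raise ValueError(f"stage {stage} outside 0..{event_set.n_events}")
    order = _check_permutation(event_set, order)
    return float(trajectory_matrix(event_set, order)[stage, biomarker])
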