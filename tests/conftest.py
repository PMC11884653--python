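"""Shared fixtures: small event sets and synthetic cohorts built at test time."""

import numpy as np
import pandas as pd
import pytest

import ppa_subtypes as pps


@pytest.fixture(scope="session")
def es3():
    """3 biomarkers x 1 threshold: 6 possible sequences, enumerable."""
    return pps.build_event_set(["A", "B", "C"], (1.0,))


@pytest.fixture(scope="session")
def es_small():
    """6 biomarkers x 1 threshold: small but non-trivial."""
    return pps.build_event_set(list("ABCDEF"), (1.0,))


@pytest.fixture(scope="session")
def es19():
    """The primary configuration: 19 ROIs x thresholds (1, 2, 3)."""
    return pps.build_event_set(pps.ROI_NAMES, (1.0, 2.0, 3.0))


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-conditions cohort with follow-ups, plus its w-scores."""
    cfg = pps.SyntheticConfig(n_patients=60, n_controls=80, seed=123)
    table, truth = pps.generate_dataset(cfg)
    controls = table[table.group == "control"]
    patients = table[table.group == "patient"]
    cov = pps.fit_control_model(controls)
    W = pps.compute_wscores(patients, cov)
    return {"config": cfg, "table": table, "truth": truth, "controls": controls,
            "patients": patients, "cov_model": cov, "W": W}


def planted_w(event_set, sequence, stages, noise_sd, rng):
    """w-score rows at given true stages of one sequence plus Gaussian noise."""
    E = pps.trajectory_matrix(event_set, sequence)
    W = E[np.asarray(stages)]
    if noise_sd > 0:
        W = W + rng.normal(0.0, noise_sd, W.shape)
    return W


@pytest.fixture(scope="session")
def planted_w_factory():
    return planted_w


def enumerate_sequences(event_set):
    """All canonical event orderings (within-biomarker thresholds ascending)."""
    import itertools

    from ppa_subtypes.events import canonicalize_sequence

    seen, out = set(), []
    for perm in itertools.permutations(range(event_set.n_events)):
        canon = tuple(canonicalize_sequence(event_set, np.array(perm)))
        if canon not in seen:
            seen.add(canon)
            out.append(np.array(canon))
    return out


@pytest.fixture(scope="session")
def sequence_enumerator():
    return enumerate_sequences
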