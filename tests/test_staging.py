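"""Posterior subtyping and staging, the stage-zero rule, external assignment."""

import numpy as np
import pandas as pd
import pytest

import ppa_subtypes as pps
from conftest import planted_w


@pytest.fixture(scope="module")
def model19(es19):
    seqs = pps.default_truth_sequences(es19, 4)
    return pps.SubtypeModel(es19, seqs, np.array([0.311, 0.269, 0.223, 0.197]),
                            np.ones(19))


def test_joint_posterior_normalizes(model19):
    rng = np.random.default_rng(0)
    post = pps.posterior(rng.normal(1.0, 1.0, 19), model19)
    assert post["joint"].sum() == pytest.approx(1.0, abs=1e-10)
    assert post["stage_posterior"].sum() == pytest.approx(1.0, abs=1e-10)
    assert post["subtype_posterior"].sum() == pytest.approx(1.0, abs=1e-10)


def test_zero_row_gives_stage_zero_dominance(model19):
    post = pps.posterior(np.zeros(19), model19)
    assert post["stage_posterior"][0] > post["stage_posterior"][1:].max()


def test_all_zero_rows_unsubtypable_in_every_case(model19):
    W = pd.DataFrame(np.zeros((50, 19)), columns=model19.event_set.biomarker_names)
    rec = pps.assign_table(W, model19)
    assert (rec.stage == 0).all()
    assert (~rec.subtypable).all()
    assert rec.subtype.isna().all()
    assert rec.assignment_probability.isna().all()


def test_noise_free_pattern_maps_to_its_subtype_and_stage(model19):
    """A row equal to subtype 2's expected values at stage 30 is assigned (2, 30)."""
    E2 = pps.trajectory_matrix(model19.event_set, model19.sequences[1])
    post = pps.posterior(E2[30], model19)
    c, k = np.unravel_index(post["joint"].argmax(), post["joint"].shape)
    assert (c + 1, k) == (2, 30)
    rec = pps.assign(E2[30], model19)
    assert rec["subtype"] == 2 and rec["stage"] == 30
    assert rec["assignment_probability"] >= 0.75


def test_late_stage_subjects_assigned_with_high_probability(model19):
    """Noise-free late-stage patterns get confident subtype assignments."""
    for c in range(4):
        E = pps.trajectory_matrix(model19.event_set, model19.sequences[c])
        rec = pps.assign(E[40], model19)
        assert rec["subtype"] == c + 1
        assert rec["assignment_probability"] >= 0.75


def test_monotone_severity_never_decreases_assigned_stage(model19):
    """Moving along a subtype's own trajectory from stage k to k' > k."""
    E3 = pps.trajectory_matrix(model19.event_set, model19.sequences[2])
    stages = [pps.assign(E3[k], model19)["stage"] for k in range(0, 57, 3)]
    assert np.all(np.diff(stages) >= 0)


def test_assignment_invariant_to_subtype_relabeling(model19):
    rng = np.random.default_rng(4)
    W = pd.DataFrame(rng.normal(1.0, 1.0, (30, 19)),
                     columns=model19.event_set.biomarker_names)
    rec = pps.assign_table(W, model19)
    perm = np.array([2, 0, 3, 1])  # new c = position of old c
    permuted = pps.SubtypeModel(model19.event_set, model19.sequences[perm],
                                model19.fractions[perm], model19.sigma)
    rec_p = pps.assign_table(W, permuted)
    np.testing.assert_array_equal(rec.stage, rec_p.stage)
    inv = np.empty(4, dtype=int)
    inv[perm] = np.arange(4)
    expected = rec.subtype.map(lambda c: inv[c - 1] + 1 if pd.notna(c) else c)
    assert rec_p.subtype.equals(expected.astype("Int64"))


def test_joint_mode_matches_joint_argmax(model19):
    rng = np.random.default_rng(6)
    W = pd.DataFrame(rng.normal(0.8, 1.0, (20, 19)),
                     columns=model19.event_set.biomarker_names)
    from ppa_subtypes.staging import joint_log_posterior

    rec = pps.assign_table(W, model19, mode="joint")
    lp = joint_log_posterior(W, model19)
    flat = lp.reshape(20, -1).argmax(axis=1)
    np.testing.assert_array_equal(rec.stage, flat % 58)


def test_external_cohort_identical_to_training_is_idempotent(small_cohort, es19):
    truth = small_cohort["truth"]
    model = pps.SubtypeModel(es19, truth.sequences,
                             np.asarray(small_cohort["config"].subtype_fractions),
                             np.ones(19))
    rec_int = pps.assign_table(small_cohort["W"], model)
    rec_ext = pps.assign_external(small_cohort["patients"], small_cohort["controls"], model)
    pd.testing.assert_frame_equal(rec_int.reset_index(drop=True), rec_ext.reset_index(drop=True))


def test_external_roi_mismatch_is_an_explicit_error(small_cohort, es19):
    model = pps.SubtypeModel(es19, pps.default_truth_sequences(es19, 1),
                             np.array([1.0]), np.ones(19))
    bad = small_cohort["patients"].drop(columns=["left_insula"])
    with pytest.raises(pps.ConfigurationError, match="left_insula"):
        pps.assign_external(bad, small_cohort["controls"], model)


def test_external_subject_at_control_prediction_lands_at_stage_zero(small_cohort, es19):
    """Volumes exactly at the control prediction give w ~ 0 and stage 0."""
    truth = small_cohort["truth"]
    model = pps.SubtypeModel(es19, truth.sequences,
                             np.asarray(small_cohort["config"].subtype_fractions),
                             np.ones(19))
    controls = small_cohort["controls"]
    cov = pps.fit_control_model(controls)
    row = controls.iloc[[0]].copy()
    row["subject_id"] = "X0"
    from ppa_subtypes.wscore import _design_matrix

    X, _, _ = _design_matrix(row, cov.covariates, cov.categories)
    row[list(cov.roi_names)] = X @ cov.coefficients.to_numpy()
    rec = pps.assign_external(row, controls, model)
    assert rec.stage.iloc[0] == 0 and not rec.subtypable.iloc[0]


def test_external_scanner_offset_cohort_recovers_subtypes(small_cohort, es19):
    """Same truth, scanner-shifted volumes, own controls: accuracy within 5 pts."""
    cfg = small_cohort["config"]
    truth = small_cohort["truth"]
    model = pps.SubtypeModel(es19, truth.sequences,
                             np.asarray(cfg.subtype_fractions), np.ones(19))
    rois = list(es19.biomarker_names)

    def accuracy(rec):
        base = rec[rec.visit_index == 0].merge(
            truth.subjects[["subject_id", "true_subtype"]], on="subject_id")
        ok = base[base.subtypable]
        return (ok.subtype == ok.true_subtype).mean()

    internal = accuracy(pps.assign_table(small_cohort["W"], model))
    ext_p = small_cohort["patients"].copy()
    ext_c = small_cohort["controls"].copy()
    for df in (ext_p, ext_c):
        df[rois] = df[rois] + 300.0  # site-wide offset, absorbed by own controls
    external = accuracy(pps.assign_external(ext_p, ext_c, model))
    assert abs(external - internal) <= 0.05
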