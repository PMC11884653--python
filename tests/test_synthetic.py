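"""Synthetic cohort generator: determinism, planted structure, forward model."""

import numpy as np
import pandas as pd
import pytest

import ppa_subtypes as pps
from ppa_subtypes.synthetic import true_covariate_model


def test_same_seed_regenerates_identical_tables():
    cfg = pps.SyntheticConfig(n_patients=30, n_controls=40, seed=77)
    t1, truth1 = pps.generate_dataset(cfg)
    t2, truth2 = pps.generate_dataset(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(truth1.visits, truth2.visits)
    assert t1.to_csv(index=False) == t2.to_csv(index=False)  # byte-identical serialization


def test_different_seed_changes_the_data():
    a, _ = pps.generate_dataset(pps.SyntheticConfig(n_patients=10, n_controls=20, seed=1))
    b, _ = pps.generate_dataset(pps.SyntheticConfig(n_patients=10, n_controls=20, seed=2))
    assert not a.equals(b)


def test_subtype_proportions_converge_to_configured_fractions():
    """Multinomial law at n = 10 000: empirical fractions within 3 SE."""
    cfg = pps.SyntheticConfig(n_patients=10_000, seed=5)
    truth = pps.generate_truth(cfg)
    counts = truth.subjects.true_subtype.value_counts()
    for c, f in enumerate(cfg.subtype_fractions, start=1):
        se = np.sqrt(f * (1 - f) / 10_000)
        assert abs(counts[c] / 10_000 - f) <= 3 * se


def test_degenerate_fractions_put_everyone_in_subtype_one():
    cfg = pps.SyntheticConfig(n_patients=50, subtype_fractions=(1.0, 0.0, 0.0, 0.0), seed=3)
    truth = pps.generate_truth(cfg)
    assert (truth.subjects.true_subtype == 1).all()


def test_default_cohort_counts_match_study_structure():
    table, truth = pps.generate_dataset(pps.SyntheticConfig(seed=0))
    assert (table.group == "control").sum() == 121
    assert table[table.group == "patient"].subject_id.nunique() == 270
    followed = truth.visits[truth.visits.visit_index > 0].subject_id.nunique()
    assert followed == 137


def test_invalid_configurations_rejected():
    with pytest.raises(pps.ConfigurationError):
        pps.SyntheticConfig(subtype_fractions=(0.5, 0.4))
    with pytest.raises(pps.ConfigurationError):
        pps.SyntheticConfig(stage_rate=-1.0)
    with pytest.raises(pps.ConfigurationError):
        pps.SyntheticConfig(thresholds=(3, 2, 1))


def test_noise_free_stage_zero_subject_scores_zero_everywhere():
    cfg = pps.SyntheticConfig(n_patients=5, noise_sd=0.0, seed=9,
                              stage_distribution=np.eye(58)[0])
    table, truth = pps.generate_dataset(cfg, followups=False)
    W = pps.compute_wscores(table[table.group == "patient"], true_covariate_model(cfg))
    np.testing.assert_allclose(W.to_numpy(), 0.0, atol=1e-9)


def test_single_biomarker_threshold_crossing_recovers_exact_wscore():
    """1-ROI model, subject at the stage of the threshold-2 event: w = 2 exactly."""
    stage_p = np.zeros(4)
    stage_p[2] = 1.0  # stage 2 = threshold-2 event of the only biomarker
    cfg = pps.SyntheticConfig(n_patients=4, n_controls=30,
                              roi_names=("left_hippocampus",),
                              subtype_fractions=(1.0,), noise_sd=0.0,
                              stage_distribution=stage_p, seed=2)
    table, truth = pps.generate_dataset(cfg, followups=False)
    W = pps.compute_wscores(table[table.group == "patient"], true_covariate_model(cfg))
    np.testing.assert_allclose(W.to_numpy(), 2.0, atol=1e-9)


def test_followup_stage_rate_zero_keeps_stages_flat():
    cfg = pps.SyntheticConfig(n_patients=30, stage_rate=0.0, seed=4)
    _, truth = pps.generate_dataset(cfg)
    v = truth.visits.pivot_table(index="subject_id", columns="visit_index",
                                 values="true_stage")
    both = v.dropna()
    assert (both[0] == both[1]).all()


def test_followup_stage_capped_at_n_events():
    stage_p = np.zeros(58)
    stage_p[54] = 1.0  # baseline three stages below the ceiling
    cfg = pps.SyntheticConfig(n_patients=30, stage_rate=10.0,
                              stage_distribution=stage_p, seed=6)
    _, truth = pps.generate_dataset(cfg)
    fu = truth.visits[truth.visits.visit_index > 0]
    assert (fu.true_stage <= 57).all()
    assert (fu.true_stage == 57).mean() > 0.9  # ~1 year at 10 stages/yr overshoots


def test_followup_stages_non_decreasing_within_subject():
    cfg = pps.SyntheticConfig(n_patients=60, n_followup_visits=3, seed=8)
    _, truth = pps.generate_dataset(cfg)
    for _, g in truth.visits.sort_values("visit_index").groupby("subject_id"):
        assert np.all(np.diff(g.true_stage.to_numpy()) >= 0)


def test_scanner_changes_at_roughly_configured_rate():
    cfg = pps.SyntheticConfig(seed=10)
    _, truth = pps.generate_dataset(cfg)
    v = truth.visits.merge(truth.subjects[["subject_id", "scanner"]],
                           on="subject_id", suffixes=("", "_baseline"))
    fu = v[v.visit_index == 1]
    switched = (fu.scanner != fu.scanner_baseline).mean()
    se = np.sqrt(0.2 * 0.8 / len(fu))
    assert abs(switched - 0.2) <= 3.5 * se


def test_noise_free_round_trip_recovers_every_true_stage_exactly():
    """wscoring -> assignment at noise 0 (exact covariate model, joint mode)."""
    prog = np.zeros(58)
    prog[1:41] = 1 / 40
    cfg = pps.SyntheticConfig(n_patients=80, noise_sd=0.0,
                              stage_distribution=prog, seed=12)
    table, truth = pps.generate_dataset(cfg)
    W = pps.compute_wscores(table[table.group == "patient"], true_covariate_model(cfg))
    model = pps.SubtypeModel(truth.event_set, truth.sequences,
                             np.asarray(cfg.subtype_fractions), np.ones(19))
    rec = pps.assign_table(W, model, mode="joint")
    rec = rec.merge(truth.visits, on=["subject_id", "visit_index"])
    assert (rec.stage == rec.true_stage).all()
    base = rec[rec.visit_index == 0].merge(truth.subjects[["subject_id", "true_subtype"]],
                                           on="subject_id")
    assert (base.subtype == base.true_subtype).all()


def test_planted_sequences_are_valid_and_distinct(es19):
    seqs = pps.default_truth_sequences(es19, 4)
    for s in seqs:
        assert np.array_equal(np.sort(s), np.arange(57))
        pos = np.empty(57, dtype=int)
        pos[s] = np.arange(57)
        for b in range(19):
            assert np.all(np.diff(pos[es19.events_of(b)]) > 0)
    # distinct onset regions: the first two events share no biomarker across
    # subtypes (later events may overlap, as real atrophy patterns do)
    for a in range(4):
        for b in range(a + 1, 4):
            early_a = set(es19.event_biomarker[seqs[a][:2]])
            early_b = set(es19.event_biomarker[seqs[b][:2]])
            assert not early_a & early_b
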