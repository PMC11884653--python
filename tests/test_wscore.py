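"""Control regression and w-score computation."""

import numpy as np
import pandas as pd
import pytest

import ppa_subtypes as pps
from ppa_subtypes.wscore import WScoreError


def _table(n, volume, age=None, sex=None, scanner=None, tiv=None, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "subject_id": [f"c{i}" for i in range(n)],
        "visit_index": 0, "group": "control", "diagnosis": "control",
        "age": age if age is not None else rng.uniform(50, 80, n).round(1),
        "sex": sex if sex is not None else rng.choice(["F", "M"], n),
        "tiv": tiv if tiv is not None else rng.normal(1.4e6, 1e5, n),
        "scanner": scanner if scanner is not None else rng.choice(["s1", "s2"], n),
        "roi": volume,
    })


def test_constant_volume_gives_intercept_and_zero_slopes():
    """Zero-effect covariates: slopes vanish and the intercept is the mean."""
    from ppa_subtypes.wscore import _design_matrix

    rng = np.random.default_rng(1)
    noise = rng.normal(0, 5.0, 60)
    # centred numeric covariate so the intercept is estimated at the data mean
    t = _table(60, 1000.0 + noise, age=rng.uniform(-5, 5, 60), rng=rng)
    m = pps.fit_control_model(t, covariates=("age", "sex", "scanner"))
    X, terms, _ = _design_matrix(t, m.covariates, m.categories)
    se = pd.Series(np.sqrt(np.diag(np.linalg.inv(X.T @ X))) * m.residual_sd["roi"],
                   index=terms)
    assert abs(m.coefficients.loc["intercept", "roi"] - 1000.0) <= 3 * se["intercept"]
    for term in terms[1:]:
        assert abs(m.coefficients.loc[term, "roi"]) <= 3 * se[term]
    assert m.residual_sd["roi"] == pytest.approx(noise.std(ddof=1), rel=0.2)


def test_exact_linear_relation_recovered_on_hand_written_rows():
    """volume = 2 * age exactly: age coefficient 2.0, residual SD at the guard."""
    age = np.array([50.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0])
    t = _table(7, 2.0 * age, age=age, sex=["F"] * 7, scanner=["s1"] * 7,
               tiv=np.full(7, 1.4e6))
    m = pps.fit_control_model(t, covariates=("age",))
    assert m.coefficients.loc["age", "roi"] == pytest.approx(2.0, abs=1e-9)
    assert m.residual_sd["roi"] == pytest.approx(1e-8)


def test_generator_coefficients_recovered_within_three_standard_errors():
    from ppa_subtypes.wscore import _design_matrix

    cfg = pps.SyntheticConfig(n_controls=400, seed=20)
    table, _ = pps.generate_dataset(cfg, followups=False)
    controls = table[table.group == "control"]
    m = pps.fit_control_model(controls)
    eff = cfg.covariate_effects
    X, terms, _ = _design_matrix(controls, m.covariates, m.categories)
    se_unit = np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
    truth = {"age": eff.age, "sex[M]": eff.sex_male, "tiv": eff.tiv}
    for roi in ("left_insula", "left_hippocampus"):
        se = pd.Series(se_unit * m.residual_sd[roi], index=terms)
        for term, expected in truth.items():
            assert abs(m.coefficients.loc[term, roi] - expected) <= 3 * se[term]


def test_in_sample_control_scores_are_centred_and_unit_scaled():
    """OLS residual identity: mean 0; SD (with the fit's dof correction) = 1."""
    cfg = pps.SyntheticConfig(seed=21)
    table, _ = pps.generate_dataset(cfg, followups=False)
    controls = table[table.group == "control"]
    m = pps.fit_control_model(controls)
    Wc = pps.compute_wscores(controls, m)
    n, p = len(controls), len(m.coefficients)
    for roi in m.roi_names:
        col = Wc[roi].to_numpy()
        assert abs(col.mean()) < 1e-8
        sd = np.sqrt((col**2).sum() / (n - p))
        assert 0.99 <= sd <= 1.01


def test_direct_formula_with_sign_flip():
    """predicted 100, observed 94, residual SD 3 -> raw -2, output +2."""
    coef = pd.DataFrame({"roi": [100.0]}, index=["intercept"])
    m = pps.CovariateModel((), ("roi",), coef, pd.Series({"roi": 3.0}), {}, 10)
    row = _table(1, np.array([94.0]))
    assert pps.compute_wscores(row, m).iloc[0, 0] == pytest.approx(2.0)
    assert pps.compute_wscores(row, m, sign_flip=False).iloc[0, 0] == pytest.approx(-2.0)


def test_affine_equivariance_under_global_volume_rescaling(small_cohort):
    """Scaling all volumes and TIV by a > 0 leaves w-scores unchanged."""
    controls, patients = small_cohort["controls"], small_cohort["patients"]
    W = pps.compute_wscores(patients, pps.fit_control_model(controls))
    a = 1.7
    rois = list(small_cohort["cov_model"].roi_names)
    c2, p2 = controls.copy(), patients.copy()
    c2[rois + ["tiv"]] *= a
    p2[rois + ["tiv"]] *= a
    W2 = pps.compute_wscores(p2, pps.fit_control_model(c2))
    np.testing.assert_allclose(W2.to_numpy(), W.to_numpy(), atol=1e-7)


def test_scanner_offset_absorbed_by_scanner_covariate(small_cohort):
    """Adding a constant to one scanner group (everywhere) leaves its w-scores unchanged."""
    controls, patients = small_cohort["controls"], small_cohort["patients"]
    rois = list(small_cohort["cov_model"].roi_names)
    W = pps.compute_wscores(patients, pps.fit_control_model(controls))
    c2, p2 = controls.copy(), patients.copy()
    for df in (c2, p2):
        mask = df.scanner == "SiemensTrio3T"
        df.loc[mask, rois] = df.loc[mask, rois] + 500.0
    W2 = pps.compute_wscores(p2, pps.fit_control_model(c2))
    np.testing.assert_allclose(W2.to_numpy(), W.to_numpy(), atol=1e-7)


def test_unseen_scanner_category_is_an_explicit_error(small_cohort):
    patients = small_cohort["patients"].copy()
    patients.loc[patients.index[0], "scanner"] = "PhilipsAchieva3T"
    with pytest.raises(WScoreError, match="PhilipsAchieva3T"):
        pps.compute_wscores(patients, small_cohort["cov_model"])


def test_missing_covariate_and_duplicate_controls_rejected(small_cohort):
    controls = small_cohort["controls"]
    dup = pd.concat([controls, controls.iloc[:1]], ignore_index=True)
    with pytest.raises(WScoreError):
        pps.fit_control_model(dup)
    nan = controls.copy()
    nan.loc[nan.index[0], "age"] = np.nan
    with pytest.raises(WScoreError):
        pps.fit_control_model(nan)


def test_collinear_covariates_rejected(small_cohort):
    controls = small_cohort["controls"].copy()
    controls["age2"] = controls["age"] * 2.0
    with pytest.raises(WScoreError, match="collinear"):
        pps.fit_control_model(controls, covariates=("age", "age2"))


def test_ols_agrees_with_statsmodels_reference(small_cohort):
    """Independent cross-check of the regression behind the w-scores."""
    sm = pytest.importorskip("statsmodels.api")
    controls = small_cohort["controls"]
    m = small_cohort["cov_model"]
    X = pd.get_dummies(controls[["age", "tiv", "sex", "scanner"]],
                       columns=["sex", "scanner"], drop_first=True, dtype=float)
    X = sm.add_constant(X)
    for roi in ("left_insula", "left_precuneus"):
        fit = sm.OLS(controls[roi].to_numpy(), X.to_numpy()).fit()
        ours = m.coefficients[roi]
        np.testing.assert_allclose(
            np.sort(fit.params), np.sort(ours.to_numpy()), rtol=1e-8)
        assert np.sqrt(fit.mse_resid) == pytest.approx(m.residual_sd[roi], rel=1e-8)
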