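"""Median curves, MoM computation, covariate adjustment and MoM ratios."""

import numpy as np
import pandas as pd
import pytest

from momscreen import (AnalyteSpec, GeneratorConfig, apply_adjustment,
                       apply_detection_filter, assign_splits, compute_mom,
                       compute_log_mom_table, fit_adjustment, fit_median_curve,
                       fit_median_curves, generate_cohort, impute_below_lod,
                       mom_ratio)
from momscreen.mom import MedianCurve


def test_constant_data_gives_flat_curve():
    ga = np.repeat([58, 66, 73, 81, 88, 95], 10)
    curve = fit_median_curve(ga, np.full(60, 10.0), "x")
    assert curve.predict(56) == pytest.approx(10.0)
    assert curve.predict(97) == pytest.approx(10.0)
    assert curve.slope == pytest.approx(0.0, abs=1e-12)


def test_three_point_weighted_fit_matches_exact_wls():
    # weekly medians 10, 20, 40 at weeks 8, 9, 10 with equal n: exactly
    # log-linear, slope log10(2) per week = log10(2)/7 per day
    ga = np.repeat([58, 65, 72], 5)  # weeks 8, 9, 10
    conc = np.repeat([10.0, 20.0, 40.0], 5)
    curve = fit_median_curve(ga, conc, "x")
    assert curve.slope == pytest.approx(np.log10(2) / 7)
    assert curve.predict(59) == pytest.approx(10.0)  # week-8 midpoint
    assert [w for w, _, _ in curve.weekly_medians] == [8, 9, 10]


def test_weight_scale_invariance_of_wls():
    rng = np.random.default_rng(0)
    ga = rng.integers(56, 98, 200)
    conc = 10 ** (1 + 0.004 * ga + rng.normal(0, 0.1, 200))
    c1 = fit_median_curve(ga, conc)
    # doubling every subject (hence every weekly n) leaves the fit unchanged
    c2 = fit_median_curve(np.tile(ga, 2), np.tile(conc, 2))
    assert c1.slope == pytest.approx(c2.slope)
    assert c1.intercept == pytest.approx(c2.intercept)


def test_curve_requires_two_weeks_and_positive_values():
    with pytest.raises(ValueError, match="2 completed"):
        fit_median_curve([58, 59, 60], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="positive"):
        fit_median_curve([58, 66], [1.0, -2.0])


def test_compute_mom_definition():
    curve = MedianCurve("x", intercept=1.0, slope=0.0)  # median 10 everywhere
    assert compute_mom(10.0, curve, 70) == pytest.approx(1.0)
    assert compute_mom(20.0, curve, 70) == pytest.approx(2.0)
    assert compute_mom(7.9, curve, 70) == pytest.approx(0.79)
    with pytest.raises(ValueError):
        compute_mom(10.0, curve, 120)  # GA out of range
    with pytest.raises(ValueError):
        compute_mom(-1.0, curve, 70)


def test_mom_ratio_basics():
    ctrl = np.array([0.8, 1.0, 1.2, 0.9, 1.1])
    assert mom_ratio(ctrl, ctrl) == 1.0
    assert mom_ratio(ctrl * 0.72, ctrl) == pytest.approx(0.72)
    assert mom_ratio(ctrl * 0.72, ctrl, method="geometric") == pytest.approx(0.72)
    with pytest.raises(ValueError):
        mom_ratio([], ctrl)


# --- pipeline-level MoM invariants ------------------------------------------


def _normalized_cohort(cfg, seed_split=3):
    subjects, matrix = generate_cohort(cfg)
    filtered, _ = apply_detection_filter(matrix)
    imputed = impute_below_lod(filtered)
    splits = assign_splits(subjects, seed=seed_split)
    train_ids = splits.subjects_in("train")
    tc = subjects[subjects["subject_id"].isin(train_ids)
                  & (subjects["group"] == "control")]
    curves = fit_median_curves(subjects, imputed, tc["subject_id"])
    log_mom = compute_log_mom_table(imputed, subjects, curves)
    return subjects, tc, log_mom


def test_training_control_week_medians_are_one():
    cfg = GeneratorConfig(
        n_controls=15000, n_eo=0, n_lo=3,
        analytes=(AnalyteSpec("x", "amine", median_intercept=80.0,
                              median_slope=0.002),), seed=21)
    subjects, tc, log_mom = _normalized_cohort(cfg)
    moms = 10 ** log_mom.loc[tc["subject_id"], "x"]
    weeks = tc.set_index("subject_id")["ga_sampling_days"] // 7
    for week, sub in moms.groupby(weeks):
        assert len(sub) >= 50
        assert sub.median() == pytest.approx(1.0, abs=0.03)
    # log10 MoM of the median control is ~0
    assert np.median(log_mom.loc[tc["subject_id"], "x"]) == pytest.approx(0, abs=0.02)


def test_mom_is_scale_equivariant(small_cohort):
    subjects, matrix = small_cohort
    filtered, _ = apply_detection_filter(matrix)
    imputed = impute_below_lod(filtered)
    splits = assign_splits(subjects, seed=1)
    tc = subjects[subjects["subject_id"].isin(splits.subjects_in("train"))
                  & (subjects["group"] == "control")]
    curves = fit_median_curves(subjects, imputed, tc["subject_id"])
    log_mom = compute_log_mom_table(imputed, subjects, curves)

    scaled = imputed.copy()
    scaled.values["taurine"] *= 37.5  # unit change is absorbed by the curve refit
    curves2 = fit_median_curves(subjects, scaled, tc["subject_id"])
    log_mom2 = compute_log_mom_table(scaled, subjects, curves2)
    np.testing.assert_allclose(log_mom2["taurine"], log_mom["taurine"], atol=1e-10)


# --- covariate adjustment ----------------------------------------------------


def test_empty_adjustment_is_identity(small_cohort):
    subjects, _ = small_cohort
    log_mom = pd.DataFrame(np.random.default_rng(0).normal(0, 0.1, (len(subjects), 1)),
                           index=subjects["subject_id"], columns=["x"])
    models = fit_adjustment(subjects, log_mom, covariates=())
    assert all(m.is_identity for m in models.values())
    out = apply_adjustment(log_mom, models, subjects)
    pd.testing.assert_frame_equal(out, log_mom)


def test_weight_effect_recovered_and_removed():
    cfg = GeneratorConfig(
        n_controls=2000, n_eo=0, n_lo=3,
        analytes=(AnalyteSpec("x", "amine", median_intercept=50.0,
                              weight_effect=-0.002),), seed=13)
    subjects, tc, log_mom = _normalized_cohort(cfg)
    models = fit_adjustment(tc, log_mom.loc[tc["subject_id"]],
                            covariates=("weight_kg",))
    m = models["x"]
    assert not m.is_identity
    # oracle: plain least squares on the same generated data
    w = tc.set_index("subject_id")["weight_kg"].to_numpy()
    y = log_mom.loc[tc["subject_id"], "x"].to_numpy()
    slope_ols = np.polyfit(w, y, 1)[0]
    assert m.coefficients["weight_kg"] == pytest.approx(slope_ols, rel=1e-6)
    assert m.coefficients["weight_kg"] == pytest.approx(-0.002, abs=5e-4)

    adjusted = apply_adjustment(log_mom, models, subjects)
    resid_slope = np.polyfit(w, adjusted.loc[tc["subject_id"], "x"].to_numpy(), 1)[0]
    assert resid_slope == pytest.approx(0.0, abs=1e-10)
    # subject at the covariate mean is (essentially) unchanged
    i = np.argmin(np.abs(w - w.mean()))
    sid = tc["subject_id"].iloc[i]
    delta = abs(adjusted.loc[sid, "x"] - log_mom.loc[sid, "x"])
    assert delta <= abs(m.coefficients["weight_kg"]) * abs(w[i] - w.mean()) + 1e-12


def test_constant_covariate_skipped_with_warning(caplog):
    import logging
    subjects = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(30)],
        "weight_kg": np.full(30, 65.0),  # constant
        "smoking": [False, True] * 15,
    })
    log_mom = pd.DataFrame(np.random.default_rng(1).normal(0, 0.1, (30, 1)),
                           index=subjects["subject_id"], columns=["x"])
    with caplog.at_level(logging.WARNING):
        models = fit_adjustment(subjects, log_mom,
                                covariates=("weight_kg", "smoking"))
    assert "constant" in caplog.text
    assert "weight_kg" not in models["x"].gate_p


def test_missing_covariate_names_subject(small_cohort):
    subjects, _ = small_cohort
    log_mom = pd.DataFrame(0.0, index=subjects["subject_id"], columns=["x"])
    models = {"x": __import__("momscreen").AdjustmentModel(
        "x", coefficients={"weight_kg": -0.002}, centers={"weight_kg": 65.0})}
    broken = subjects.copy()
    broken.loc[3, "weight_kg"] = np.nan
    sid = broken.loc[3, "subject_id"]
    with pytest.raises(ValueError, match=sid):
        apply_adjustment(log_mom, models, broken)
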