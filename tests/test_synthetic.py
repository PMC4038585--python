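"""Cohort generator: determinism, effect-size calibration, censoring, fixtures."""

import numpy as np
import pandas as pd
import pytest

from momscreen import (AnalyteSpec, GeneratorConfig, MapSpec, RiskModel,
                       generate_cohort, generate_from_risk_model, read_fixture,
                       write_fixture)
from momscreen.synthetic import ConfigurationError, validate_subjects


def test_group_sizes_and_labels(small_cohort, small_config):
    subjects, matrix = small_cohort
    counts = subjects["group"].value_counts()
    assert counts["control"] == small_config.n_controls
    assert counts["eo_pe"] == small_config.n_eo
    assert counts["lo_pe"] == small_config.n_lo
    assert matrix.shape == (len(subjects), len(small_config.analytes))


def test_subject_invariants_hold(small_cohort):
    subjects, _ = small_cohort
    validate_subjects(subjects)  # raises on violation
    assert (subjects["dbp_mmHg"] <= subjects["sbp_mmHg"]).all()
    ga = subjects["ga_sampling_days"]
    assert ga.between(56, 97).all()
    d = subjects.set_index("group")["ga_delivery_weeks"]
    assert (d.loc["eo_pe"] < 34).all()
    assert (d.loc["lo_pe"] >= 34).all()
    assert (d.loc["control"] >= 37).all()


def test_same_seed_is_bit_identical(small_config):
    s1, m1 = generate_cohort(small_config, seed=123)
    s2, m2 = generate_cohort(small_config, seed=123)
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(m1.values, m2.values)
    assert m1 == m2
    s3, _ = generate_cohort(small_config, seed=124)
    assert not s3["weight_kg"].equals(s1["weight_kg"])


def _median_ratio(matrix, subjects, analyte, group):
    g = subjects.set_index("subject_id")["group"]
    vals = matrix.values[analyte]
    return (vals[(g == group).to_numpy()].median()
            / vals[(g == "control").to_numpy()].median())


@pytest.mark.parametrize("momr,group_kw,group", [
    (1.0, "momr_eo", "eo_pe"),       # null effect
    (0.79, "momr_eo", "eo_pe"),      # taurine-sized reduction
    (1.10, "momr_lo", "lo_pe"),      # MAP-sized increase
])
def test_momr_recovered_at_large_n(momr, group_kw, group):
    spec = AnalyteSpec("x", "amine", median_intercept=100.0,
                       median_slope=0.001, log10_mom_sd=0.1, **{group_kw: momr})
    cfg = GeneratorConfig(n_controls=5000, n_eo=5000, n_lo=5000,
                          analytes=(spec,), seed=3)
    subjects, matrix = generate_cohort(cfg)
    # raw concentrations mix GA-dependence; compare within a single week bin
    wk = subjects["ga_sampling_days"] // 7
    sel = (wk == 10).to_numpy()
    ratio = _median_ratio(matrix.select_subjects(matrix.values.index[sel]),
                          subjects[sel], "x", group)
    assert ratio == pytest.approx(momr, abs=0.03)


def test_lod_censoring_calibrated():
    spec = AnalyteSpec("x", "oxylipin", median_intercept=5.0,
                       log10_mom_sd=0.15, lod_quantile=0.25)
    cfg = GeneratorConfig(n_controls=6000, n_eo=0, n_lo=0, analytes=(spec,), seed=5)
    _, matrix = generate_cohort(cfg)
    frac = matrix.below_lod_mask["x"].mean()
    assert frac == pytest.approx(0.25, abs=0.02)
    assert "x" in matrix.lod
    detected = matrix.values["x"].dropna()
    assert (detected >= matrix.lod["x"]).all()


def test_map_identity_round_trips(small_cohort):
    subjects, _ = small_cohort
    recomposed = subjects["dbp_mmHg"] + (subjects["sbp_mmHg"]
                                         - subjects["dbp_mmHg"]) / 3.0
    assert np.all(recomposed > 0)
    # MAP MoM is log-Gaussian around the configured median in controls
    ctrl = recomposed[subjects["group"] == "control"]
    assert 75 < ctrl.median() < 95


def test_invalid_specs_rejected():
    with pytest.raises(ConfigurationError):
        AnalyteSpec("bad", "amine", log10_mom_sd=0.0)
    with pytest.raises(ConfigurationError):
        AnalyteSpec("bad", "amine", momr_eo=-1.0)
    with pytest.raises(ConfigurationError):
        AnalyteSpec("bad", "amine", lod_quantile=1.0)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(n_controls=-1)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(ga_sampling_range=(40, 97))


def test_optional_correlation_structure():
    specs = (AnalyteSpec("a", "amine"), AnalyteSpec("b", "amine"))
    corr = np.array([[1.0, 0.8], [0.8, 1.0]])
    cfg = GeneratorConfig(n_controls=4000, n_eo=0, n_lo=0, analytes=specs,
                          correlation=corr, seed=9)
    subjects, matrix = generate_cohort(cfg)
    wk = (subjects["ga_sampling_days"] // 7).to_numpy()
    log = np.log10(matrix.values.to_numpy())
    # partial out the GA trend by correlating within one week bin
    sel = wk == 11
    r = np.corrcoef(log[sel, 0], log[sel, 1])[0, 1]
    assert r == pytest.approx(0.8, abs=0.08)


# --- outcome generation from a known logistic rule ---------------------------


def test_null_rule_gives_half_rate():
    model = RiskModel("eo_pe", (), 0.0, ())
    tab = generate_from_risk_model(model, {}, n=20000, seed=1)
    assert tab["outcome"].mean() == pytest.approx(0.5, abs=0.02)


def test_intercept_only_rate_matches_closed_form():
    # logistic(-2.999) = 0.04747
    model = RiskModel("eo_pe", (), -2.999, ())
    tab = generate_from_risk_model(model, {}, n=50000, seed=2)
    assert tab["outcome"].mean() == pytest.approx(0.047471, abs=0.005)


def test_printed_rule_rate_below_half():
    model = RiskModel("eo_pe", ("MAP", "taurine"), -2.999, (33.491, -2.490))
    cov = {"MAP": ("normal", 0.0, 0.05), "taurine": ("normal", 0.0, 0.1)}
    tab = generate_from_risk_model(model, cov, n=5000, seed=3)
    assert tab["outcome"].mean() < 0.5
    assert set(tab.columns) == {"MAP", "taurine", "outcome"}


def test_missing_term_named_in_error():
    model = RiskModel("eo_pe", ("MAP", "taurine"), 0.0, (1.0, 1.0))
    with pytest.raises(KeyError, match="taurine"):
        generate_from_risk_model(model, {"MAP": ("normal", 0, 1)}, n=10)


# --- fixture round-trip ------------------------------------------------------


def test_fixture_round_trip(tmp_path, small_cohort):
    subjects, matrix = small_cohort
    write_fixture(subjects, matrix, tmp_path)
    subjects2, matrix2 = read_fixture(tmp_path)
    pd.testing.assert_frame_equal(
        subjects.reset_index(drop=True), subjects2.reset_index(drop=True),
        check_dtype=False)
    assert matrix2 == matrix
    pd.testing.assert_frame_equal(matrix.below_lod_mask, matrix2.below_lod_mask)


def test_fixture_rejects_negative_concentration(tmp_path, small_cohort):
    subjects, matrix = small_cohort
    write_fixture(subjects, matrix, tmp_path)
    path = tmp_path / "measurements.csv"
    lines = path.read_text().splitlines()
    parts = lines[1].split(",")
    parts[1] = "-5.0"
    lines[1] = ",".join(parts)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="non-positive"):
        read_fixture(tmp_path)
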