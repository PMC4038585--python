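"""Gestation-specific multiple-of-the-median (MoM) normalization.

A marker's raw concentration depends strongly on gestational age at sampling,
so levels are expressed as multiples of the gestation-specific normal median:
``MoM = value / expected_median(GA)``.  Expected medians come from a weighted
regression of ``log10(median concentration)`` per completed gestational week
on the week midpoint (in days) among the *training-set controls only*, each
week weighted by the number of women it contributes.  Log10 MoMs are then
adjusted for maternal covariates (weight, smoking, ethnicity) where those
covariates are significantly associated with the marker among training
controls — the standard Cuckle–Wald adjustment, applied subtractively on the
log scale and centred so that an average-covariate control is unchanged.
Gestation itself is handled by the median curve and is not re-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GA_MAX_DAYS, GA_MIN_DAYS, MeasurementMatrix

__all__ = [
    "MedianCurve",
    "AdjustmentModel",
    "fit_median_curve",
    "fit_median_curves",
    "compute_mom",
    "compute_log_mom_table",
    "fit_adjustment",
    "apply_adjustment",
    "mom_ratio",
]

logger = logging.getLogger(__name__)

#: default significance level of the covariate-adjustment gate
ADJUSTMENT_ALPHA = 0.05


@dataclass(frozen=True)
class MedianCurve:
    """Fitted gestational-age-to-expected-median mapping for one analyte.

    ``log10(median) = intercept + slope * GA_days``; ``weekly_medians`` keeps
    the (completed week, median, n) points that entered the weighted fit.
    """

    analyte: str
    intercept: float
    slope: float
    weekly_medians: tuple[tuple[int, float, int], ...] = ()

    def predict(self, ga_days):
        """Expected control median concentration at ``ga_days``."""
        ga = np.asarray(ga_days, float)
        out = 10.0 ** (self.intercept + self.slope * ga)
        return float(out) if out.ndim == 0 else out


def completed_week(ga_days) -> np.ndarray:
    """Completed gestational week of a GA in days (half-open 7-day bins)."""
    return np.asarray(ga_days, int) // 7


def fit_median_curve(ga_days, concentrations, analyte: str = "") -> MedianCurve:
    """Weighted regression of weekly median concentrations on gestational age.

    Per completed week, the median concentration and count ``n`` are computed;
    ``log10(median)`` is regressed on the week midpoint in days by weighted
    least squares with weights ``n``.  Requires values from at least two
    distinct completed weeks and strictly positive concentrations.
    """
    ga = np.asarray(ga_days, float)
    conc = np.asarray(concentrations, float)
    if ga.shape != conc.shape:
        raise ValueError("gestational ages and concentrations differ in length")
    if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
        raise ValueError(f"{analyte or 'analyte'}: concentrations must be positive "
                         "and finite (impute below-LOD values first)")
    weeks = completed_week(ga)
    uniq = np.unique(weeks)
    if len(uniq) < 2:
        raise ValueError(f"{analyte or 'analyte'}: need >= 2 completed gestational "
                         f"weeks to fit a median curve (got {len(uniq)})")
    pts = []
    for w in uniq:
        sel = conc[weeks == w]
        pts.append((int(w), float(np.median(sel)), int(sel.size)))
    x = np.array([7 * w + 3 for w, _, _ in pts], float)  # week midpoint in days
    y = np.array([np.log10(m) for _, m, _ in pts])
    n = np.array([c for _, _, c in pts], float)
    X = np.column_stack([np.ones_like(x), x])
    wsr = np.sqrt(n)
    beta, *_ = np.linalg.lstsq(X * wsr[:, None], y * wsr, rcond=None)
    return MedianCurve(analyte, float(beta[0]), float(beta[1]), tuple(pts))


def fit_median_curves(subjects: pd.DataFrame, matrix: MeasurementMatrix,
                      training_control_ids) -> dict[str, MedianCurve]:
    """Fit one :class:`MedianCurve` per analyte on the training-set controls."""
    ids = pd.Index(training_control_ids)
    ga = subjects.set_index("subject_id").loc[ids, "ga_sampling_days"]
    sub = matrix.values.loc[ids]
    return {a: fit_median_curve(ga.to_numpy(), sub[a].to_numpy(), a)
            for a in matrix.analyte_names}


def compute_mom(value, curve: MedianCurve, ga_days):
    """MoM of a concentration: ``value / expected median at ga_days``."""
    ga = np.asarray(ga_days, float)
    if np.any(ga < GA_MIN_DAYS) or np.any(ga > GA_MAX_DAYS):
        raise ValueError(f"gestational age outside [{GA_MIN_DAYS}, {GA_MAX_DAYS}] days")
    v = np.asarray(value, float)
    if np.any(v <= 0):
        raise ValueError("concentration must be positive")
    out = v / curve.predict(ga)
    return float(out) if out.ndim == 0 else out


def compute_log_mom_table(matrix: MeasurementMatrix, subjects: pd.DataFrame,
                          curves: dict[str, MedianCurve]) -> pd.DataFrame:
    """log10-MoM table (subjects x markers) for every analyte with a curve."""
    ga = subjects.set_index("subject_id").loc[matrix.values.index, "ga_sampling_days"]
    cols = {}
    for a in matrix.analyte_names:
        cols[a] = np.log10(compute_mom(matrix.values[a].to_numpy(), curves[a],
                                       ga.to_numpy()))
    return pd.DataFrame(cols, index=matrix.values.index)


# ---------------------------------------------------------------------------
# Cuckle–Wald covariate adjustment


@dataclass
class AdjustmentModel:
    """Covariate-adjustment terms for one marker's log10 MoMs.

    ``coefficients`` maps a design column (e.g. ``weight_kg`` or
    ``ethnicity=other``) to its fitted effect on log10 MoM; ``centers`` to the
    training-control mean of that column.  ``gate_p`` records the per-covariate
    screening p-values; only covariates flagged significant contribute columns.
    """

    marker: str
    coefficients: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    gate_p: dict[str, float] = field(default_factory=dict)

    @property
    def is_identity(self) -> bool:
        return not self.coefficients


def _design_columns(subjects: pd.DataFrame, covariate: str) -> dict[str, np.ndarray]:
    col = subjects[covariate]
    if col.dtype == bool or set(col.unique()) <= {0, 1, True, False}:
        return {covariate: col.astype(float).to_numpy()}
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        return {f"{covariate}={lv}": (col.astype(str) == lv).astype(float).to_numpy()
                for lv in levels[1:]}  # first level is the reference
    return {covariate: col.astype(float).to_numpy()}


def _gate_p_value(y: np.ndarray, subjects: pd.DataFrame, covariate: str) -> float:
    """Screening p-value for one covariate against log10 MoM in controls."""
    col = subjects[covariate]
    if col.dtype == bool or set(col.unique()) <= {0, 1, True, False}:
        a, b = y[col.astype(bool).to_numpy()], y[~col.astype(bool).to_numpy()]
        if len(a) < 2 or len(b) < 2:
            return 1.0
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        groups = [y[(col.astype(str) == lv).to_numpy()] for lv in col.astype(str).unique()]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            return 1.0
        return float(stats.f_oneway(*groups).pvalue)
    res = stats.linregress(col.astype(float).to_numpy(), y)
    return float(res.pvalue)


def fit_adjustment(training_controls: pd.DataFrame, log_mom_table: pd.DataFrame,
                   covariates: tuple[str, ...] = ("weight_kg", "smoking", "ethnicity"),
                   alpha: float = ADJUSTMENT_ALPHA) -> dict[str, AdjustmentModel]:
    """Per-marker covariate adjustment fitted on training-set controls.

    Each candidate covariate is screened for association with the marker's
    log10 MoMs among training controls (regression t-test for continuous,
    two-sample t-test for binary, one-way ANOVA for categorical); covariates
    with p < ``alpha`` are then fitted jointly by least squares.  A constant
    covariate is skipped with a logged warning.  With ``covariates=()`` every
    marker gets an identity adjustment.
    """
    tc = training_controls.set_index("subject_id")
    usable = []
    for cov in covariates:
        if cov not in tc.columns:
            raise KeyError(f"covariate {cov!r} missing from subject table")
        if tc[cov].nunique() < 2:
            logger.warning("covariate %r is constant among training controls; skipped",
                           cov)
            continue
        usable.append(cov)

    models: dict[str, AdjustmentModel] = {}
    sub = log_mom_table.loc[tc.index]
    for marker in log_mom_table.columns:
        y = sub[marker].to_numpy()
        model = AdjustmentModel(marker)
        flagged = []
        for cov in usable:
            p = _gate_p_value(y, tc, cov)
            model.gate_p[cov] = p
            if p < alpha:
                flagged.append(cov)
        if flagged:
            names, cols = [], []
            for cov in flagged:
                for name, arr in _design_columns(tc, cov).items():
                    names.append(name)
                    cols.append(arr)
            X = np.column_stack(cols)
            centers = X.mean(axis=0)
            Xc = np.column_stack([np.ones(len(y)), X - centers])
            beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            model.coefficients = dict(zip(names, beta[1:].astype(float)))
            model.centers = dict(zip(names, centers.astype(float)))
        models[marker] = model
    return models


def apply_adjustment(log_mom_table: pd.DataFrame, models: dict[str, AdjustmentModel],
                     subjects: pd.DataFrame) -> pd.DataFrame:
    """Subtract fitted covariate effects from log10 MoMs (centred).

    ``adjusted = raw - sum_j coef_j * (x_j - center_j)``; a subject at the
    training-control covariate mean is unchanged, as is every subject under an
    identity adjustment.  A missing covariate value raises, naming the subject.
    """
    subj = subjects.set_index("subject_id").loc[log_mom_table.index]
    out = log_mom_table.copy()
    design_cache: dict[str, np.ndarray] = {}
    for marker, model in models.items():
        if marker not in out.columns or model.is_identity:
            continue
        correction = np.zeros(len(out))
        for name, coef in model.coefficients.items():
            if name not in design_cache:
                cov = name.split("=")[0]
                if cov not in subj.columns:
                    raise KeyError(f"covariate {cov!r} missing from subject table")
                if subj[cov].isna().any():
                    who = subj.index[subj[cov].isna()][0]
                    raise ValueError(f"subject {who!r} has a missing value "
                                     f"for covariate {cov!r}")
                if "=" in name:
                    level = name.split("=", 1)[1]
                    design_cache[name] = (subj[cov].astype(str) == level).astype(float).to_numpy()
                else:
                    design_cache[name] = subj[cov].astype(float).to_numpy()
            correction += coef * (design_cache[name] - model.centers[name])
        out[marker] = out[marker] - correction
    return out


def mom_ratio(case_moms, control_moms, method: str = "median") -> float:
    """Case/control MoM ratio — the effect-size measure of the analysis.

    ``median`` (default): median(case MoMs) / median(control MoMs).
    ``geometric``: ratio of geometric means.  Inputs are MoMs (not logs).
    """
    case = np.asarray(case_moms, float)
    ctrl = np.asarray(control_moms, float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be nonempty")
    if method == "median":
        return float(np.median(case) / np.median(ctrl))
    if method == "geometric":
        return float(10.0 ** (np.mean(np.log10(case)) - np.mean(np.log10(ctrl))))
    raise ValueError(f"unknown method {method!r}")
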