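"""Synthetic case-control cohort generator.

Emulates the statistical structure of a first-trimester nested case-control
serum-screening study of preeclampsia: 500 unaffected controls, 68 early-onset
(EO-PE, delivery <34 weeks) and 99 late-onset (LO-PE, delivery >=34 weeks)
cases sampled at 8+0 to 13+6 weeks of gestation, with a targeted metabolomics
panel (amines and oxylipins) plus mean arterial pressure (MAP) treated as a
marker.

For every analyte, control concentrations at gestational age ``g`` days are

    median(g) * 10**N(0, log10_mom_sd),    median(g) = 10**(a + b*g)

so that the true multiple-of-the-median (MoM) is log-Gaussian with median 1.
Case concentrations carry an additional multiplicative MoM ratio (MoMR), the
effect-size measure used throughout: ``MoMR = median(case MoM)/median(control
MoM)``.  Below-LOD censoring masks every value under the ``lod_quantile``
point of the control marginal.  MAP is generated the same way on the MoM scale
and decomposed into systolic/diastolic pressures consistent with the identity
``MAP = DBP + (SBP - DBP)/3``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteSpec",
    "MapSpec",
    "GroupCovariates",
    "CovariateConfig",
    "GeneratorConfig",
    "MeasurementMatrix",
    "GROUPS",
    "SUBJECT_COLUMNS",
    "default_panel",
    "default_config",
    "generate_cohort",
    "generate_from_risk_model",
    "write_fixture",
    "read_fixture",
    "validate_subjects",
]

GROUPS = ("control", "eo_pe", "lo_pe")

#: column schema of the subject table (one row per pregnancy)
SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "ga_sampling_days",
    "weight_kg",
    "smoking",
    "nulliparous",
    "history_htn",
    "ethnicity",
    "sbp_mmHg",
    "dbp_mmHg",
    "ga_delivery_weeks",
    "birthweight_centile",
]

GA_MIN_DAYS, GA_MAX_DAYS = 56, 97  # 8+0 .. 13+6 weeks
GA_REF_DAYS = 77.0  # reference day at which median_intercept applies


class ConfigurationError(ValueError):
    """Raised for non-finite, non-positive or otherwise invalid generator specs."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class AnalyteSpec:
    """Generative parameters of one measured analyte.

    ``median_intercept`` is the control median concentration at the reference
    gestational age (day 77, mid-window); ``median_slope`` is the log10
    multiplicative trend per day of gestation.  ``momr_eo``/``momr_lo`` are
    case/control MoM ratios; ``lod_quantile`` the fraction of the control
    marginal censored below the limit of detection; ``weight_effect`` a log10
    MoM slope per kg of maternal weight (centred at the control mean weight).
    """

    name: str
    platform: str = "amine"  # "amine" | "oxylipin"
    median_intercept: float = 50.0
    median_slope: float = 0.0
    log10_mom_sd: float = 0.10
    momr_eo: float = 1.0
    momr_lo: float = 1.0
    lod_quantile: float = 0.0
    weight_effect: float = 0.0

    def __post_init__(self) -> None:
        _require(self.platform in ("amine", "oxylipin"),
                 f"{self.name}: unknown platform {self.platform!r}")
        for attr in ("median_intercept", "median_slope", "log10_mom_sd",
                     "momr_eo", "momr_lo", "lod_quantile", "weight_effect"):
            v = getattr(self, attr)
            _require(np.isfinite(v), f"{self.name}.{attr} is not finite")
        _require(self.median_intercept > 0, f"{self.name}: median_intercept must be > 0")
        _require(self.log10_mom_sd > 0, f"{self.name}: log10_mom_sd must be > 0")
        _require(self.momr_eo > 0 and self.momr_lo > 0,
                 f"{self.name}: MoM ratios must be > 0")
        _require(0.0 <= self.lod_quantile < 1.0,
                 f"{self.name}: lod_quantile must be in [0, 1)")


@dataclass(frozen=True)
class MapSpec:
    """Marker spec for mean arterial pressure (always fully detected)."""

    median_mmHg: float = 85.0
    median_slope: float = 0.0
    log10_mom_sd: float = 0.04
    momr_eo: float = 1.10
    momr_lo: float = 1.07
    pulse_pressure_mean: float = 40.0
    pulse_pressure_sd: float = 5.0

    def __post_init__(self) -> None:
        _require(self.median_mmHg > 0, "MAP median must be > 0")
        _require(self.log10_mom_sd > 0, "MAP log10_mom_sd must be > 0")
        _require(self.momr_eo > 0 and self.momr_lo > 0, "MAP MoM ratios must be > 0")
        _require(self.pulse_pressure_sd > 0, "pulse pressure SD must be > 0")


@dataclass(frozen=True)
class GroupCovariates:
    """Maternal-covariate distributions for one outcome group."""

    weight_mean_kg: float
    weight_sd_kg: float = 10.0
    smoking_rate: float = 0.05
    nulliparity_rate: float = 0.5
    history_htn_rate: float = 0.01

    def __post_init__(self) -> None:
        _require(self.weight_mean_kg > 0 and self.weight_sd_kg > 0,
                 "weight parameters must be > 0")
        for attr in ("smoking_rate", "nulliparity_rate", "history_htn_rate"):
            v = getattr(self, attr)
            _require(0.0 <= v <= 1.0, f"{attr} must be in [0, 1]")


@dataclass(frozen=True)
class CovariateConfig:
    """Per-group covariate distributions (defaults follow the study cohort)."""

    control: GroupCovariates = field(default_factory=lambda: GroupCovariates(
        weight_mean_kg=65.5, smoking_rate=0.042,
        nulliparity_rate=0.466, history_htn_rate=0.008))
    eo_pe: GroupCovariates = field(default_factory=lambda: GroupCovariates(
        weight_mean_kg=70.0, smoking_rate=0.118,
        nulliparity_rate=0.809, history_htn_rate=0.059))
    lo_pe: GroupCovariates = field(default_factory=lambda: GroupCovariates(
        weight_mean_kg=67.5, smoking_rate=0.061,
        nulliparity_rate=0.727, history_htn_rate=0.101))
    ethnicity_levels: tuple[str, ...] = ("european", "other")
    ethnicity_probs: tuple[float, ...] = (0.85, 0.15)

    def for_group(self, group: str) -> GroupCovariates:
        return getattr(self, group)


def default_panel() -> list[AnalyteSpec]:
    """The default 104-analyte panel: 58 amines and 46 oxylipins.

    Null effects everywhere except the three markers with published effect
    sizes (taurine MoMR 0.79 in EO-PE, asparagine 0.84 in EO-PE,
    glycylglycine 0.72 in LO-PE).  Two oxylipins are censored below the limit
    of detection in 25% of controls so the >80% detection filter has work to
    do, and two more carry mild (5%) censoring to exercise imputation.
    Median levels and gestational trends vary deterministically across the
    panel so that no two analytes share a median curve.
    """
    panel: list[AnalyteSpec] = [
        AnalyteSpec("taurine", "amine", median_intercept=120.0,
                    median_slope=-0.0010, momr_eo=0.79),
        AnalyteSpec("asparagine", "amine", median_intercept=45.0,
                    median_slope=0.0008, momr_eo=0.84),
        AnalyteSpec("glycylglycine", "amine", median_intercept=8.0,
                    median_slope=-0.0006, momr_lo=0.72),
    ]
    for i in range(55):  # remaining amines
        panel.append(AnalyteSpec(
            f"amine_{i + 4:02d}", "amine",
            median_intercept=20.0 + 7.0 * i,
            median_slope=0.0015 * np.cos(0.7 * i),
            log10_mom_sd=0.10,
            lod_quantile=0.05 if i < 2 else 0.0))
    for i in range(46):
        panel.append(AnalyteSpec(
            f"oxylipin_{i + 1:02d}", "oxylipin",
            median_intercept=1.0 + 0.45 * i,
            median_slope=0.0012 * np.sin(0.5 * i),
            log10_mom_sd=0.15,
            lod_quantile=0.25 if i < 2 else 0.0))
    return panel


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort-generator configuration; defaults reproduce the study design."""

    n_controls: int = 500
    n_eo: int = 68
    n_lo: int = 99
    ga_sampling_range: tuple[int, int] = (GA_MIN_DAYS, GA_MAX_DAYS)
    analytes: tuple[AnalyteSpec, ...] = field(default_factory=lambda: tuple(default_panel()))
    map_spec: MapSpec = field(default_factory=MapSpec)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    #: optional analyte-analyte correlation of log10 MoMs (defaults to independence)
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_controls >= 0 and self.n_eo >= 0 and self.n_lo >= 0,
                 "group sizes must be >= 0")
        lo, hi = self.ga_sampling_range
        _require(GA_MIN_DAYS <= lo <= hi <= GA_MAX_DAYS,
                 f"GA sampling range must lie within [{GA_MIN_DAYS}, {GA_MAX_DAYS}] days")
        names = [a.name for a in self.analytes]
        _require(len(names) == len(set(names)), "duplicate analyte names")
        if self.correlation is not None:
            c = np.asarray(self.correlation, float)
            k = len(self.analytes)
            _require(c.shape == (k, k), "correlation must be analytes x analytes")
            _require(np.allclose(c, c.T), "correlation must be symmetric")


class MeasurementMatrix:
    """Subjects x analytes concentration table with below-LOD missingness.

    ``values`` holds concentrations with NaN at masked (below-LOD) positions;
    ``below_lod_mask`` is a boolean frame of the same shape; ``lod`` maps an
    analyte name to its limit of detection where one applies.
    """

    def __init__(self, values: pd.DataFrame, below_lod_mask: pd.DataFrame | None = None,
                 lod: dict[str, float] | None = None):
        values = values.astype(float)
        values.index = values.index.rename("subject_id")
        values.columns = values.columns.rename(None)
        if below_lod_mask is None:
            below_lod_mask = values.isna()
        below_lod_mask = below_lod_mask.astype(bool)
        below_lod_mask.index = below_lod_mask.index.rename("subject_id")
        below_lod_mask.columns = below_lod_mask.columns.rename(None)
        if not (values.index.equals(below_lod_mask.index)
                and values.columns.equals(below_lod_mask.columns)):
            raise ValueError("values and below_lod_mask are not aligned")
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("duplicate subject ids or analyte names")
        masked = below_lod_mask.to_numpy()
        v = values.to_numpy()
        if masked.any() and not np.all(np.isnan(v[masked])):
            raise ValueError("masked positions must hold no value")
        unmasked = v[~masked]
        if unmasked.size and not np.all(np.isfinite(unmasked) & (unmasked > 0)):
            raise ValueError("all detected concentrations must be finite and > 0")
        self.values = values
        self.below_lod_mask = below_lod_mask
        self.lod = dict(lod or {})

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "MeasurementMatrix":
        return MeasurementMatrix(self.values.copy(), self.below_lod_mask.copy(),
                                 dict(self.lod))

    def select_analytes(self, names: list[str]) -> "MeasurementMatrix":
        return MeasurementMatrix(self.values[names], self.below_lod_mask[names],
                                 {k: v for k, v in self.lod.items() if k in names})

    def select_subjects(self, ids) -> "MeasurementMatrix":
        return MeasurementMatrix(self.values.loc[ids], self.below_lod_mask.loc[ids],
                                 dict(self.lod))

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementMatrix):
            return NotImplemented
        return (self.values.equals(other.values)
                and self.below_lod_mask.equals(other.below_lod_mask)
                and self.lod.keys() == other.lod.keys()
                and all(np.isclose(self.lod[k], other.lod[k]) for k in self.lod))


def default_config(**overrides) -> GeneratorConfig:
    """Study-design default configuration with keyword overrides."""
    return dataclasses.replace(GeneratorConfig(), **overrides)


# ---------------------------------------------------------------------------
# cohort generation


def _group_log_momr(spec, group: str) -> float:
    if group == "eo_pe":
        return float(np.log10(spec.momr_eo))
    if group == "lo_pe":
        return float(np.log10(spec.momr_lo))
    return 0.0


def _draw_delivery_weeks(rng: np.random.Generator, group: str, n: int) -> np.ndarray:
    # EO-PE delivers <34 wk (median ~31), LO-PE in [34, 42), controls at term
    if group == "eo_pe":
        return np.clip(rng.normal(31.0, 1.6, n), 24.0, 33.9)
    if group == "lo_pe":
        return np.clip(rng.normal(37.5, 1.6, n), 34.0, 41.9)
    return np.clip(rng.normal(40.0, 1.2, n), 37.0, 42.0)


def _draw_centile(rng: np.random.Generator, group: str, n: int) -> np.ndarray:
    # Beta shapes chosen so group medians sit near the study's 57 / 25 / 14
    if group == "eo_pe":
        return 100.0 * rng.beta(1.0, 2.4, n)
    if group == "lo_pe":
        return 100.0 * rng.beta(0.7, 2.8, n)
    return 100.0 * rng.beta(1.6, 1.25, n)


def generate_cohort(config: GeneratorConfig,
                    seed: int | None = None) -> tuple[pd.DataFrame, MeasurementMatrix]:
    """Generate one cohort: a subject table and its measurement matrix.

    Deterministic in ``(config, seed)``; ``seed`` defaults to ``config.seed``.
    Below-LOD values are masked against the empirical ``lod_quantile`` point
    of the control concentrations of each analyte, across all groups.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = {"control": config.n_controls, "eo_pe": config.n_eo, "lo_pe": config.n_lo}
    n_tot = sum(sizes.values())
    groups = np.repeat(list(sizes), list(sizes.values()))
    subject_ids = [f"S{i + 1:05d}" for i in range(n_tot)]

    ga_lo, ga_hi = config.ga_sampling_range
    ga = rng.integers(ga_lo, ga_hi + 1, n_tot)

    cov = config.covariates
    weight = np.empty(n_tot)
    smoking = np.empty(n_tot, bool)
    nullip = np.empty(n_tot, bool)
    history = np.empty(n_tot, bool)
    delivery = np.empty(n_tot)
    centile = np.empty(n_tot)
    for g in GROUPS:
        m = groups == g
        n = int(m.sum())
        gc = cov.for_group(g)
        weight[m] = np.clip(rng.normal(gc.weight_mean_kg, gc.weight_sd_kg, n), 40.0, None)
        smoking[m] = rng.random(n) < gc.smoking_rate
        nullip[m] = rng.random(n) < gc.nulliparity_rate
        history[m] = rng.random(n) < gc.history_htn_rate
        delivery[m] = _draw_delivery_weeks(rng, g, n)
        centile[m] = _draw_centile(rng, g, n)
    ethnicity = rng.choice(cov.ethnicity_levels, size=n_tot, p=cov.ethnicity_probs)

    # analyte log10-MoMs: N(0, sd) per analyte (optionally correlated), plus
    # the group effect and a maternal-weight effect centred at the control mean
    specs = config.analytes
    k = len(specs)
    sds = np.array([a.log10_mom_sd for a in specs])
    z = rng.standard_normal((n_tot, k))
    if config.correlation is not None:
        z = z @ np.linalg.cholesky(np.asarray(config.correlation, float)).T
    log_mom = z * sds
    for g in ("eo_pe", "lo_pe"):
        m = groups == g
        log_mom[m] += np.array([_group_log_momr(a, g) for a in specs])
    w_eff = np.array([a.weight_effect for a in specs])
    log_mom += np.outer(weight - cov.control.weight_mean_kg, w_eff)

    intercepts = np.array([np.log10(a.median_intercept) for a in specs])
    slopes = np.array([a.median_slope for a in specs])
    log_conc = intercepts + np.outer(ga - GA_REF_DAYS, slopes) + log_mom
    conc = 10.0 ** log_conc

    values = pd.DataFrame(conc, index=subject_ids, columns=[a.name for a in specs])
    is_control = groups == "control"
    lod: dict[str, float] = {}
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    for j, spec in enumerate(specs):
        if spec.lod_quantile > 0:
            lod_j = float(np.quantile(conc[is_control, j], spec.lod_quantile))
            lod[spec.name] = lod_j
            mask.iloc[:, j] = values.iloc[:, j] < lod_j
    values = values.mask(mask)

    # MAP on the MoM scale, then a plausible SBP/DBP pair solving the identity
    ms = config.map_spec
    map_logmom = rng.normal(0.0, ms.log10_mom_sd, n_tot)
    for g in ("eo_pe", "lo_pe"):
        m = groups == g
        map_logmom[m] += _group_log_momr(ms, g)
    map_mmHg = (10.0 ** (np.log10(ms.median_mmHg)
                         + (ga - GA_REF_DAYS) * ms.median_slope + map_logmom))
    pulse = np.clip(rng.normal(ms.pulse_pressure_mean, ms.pulse_pressure_sd, n_tot),
                    10.0, None)
    dbp = map_mmHg - pulse / 3.0
    sbp = dbp + pulse

    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "ga_sampling_days": ga,
        "weight_kg": weight,
        "smoking": smoking,
        "nulliparous": nullip,
        "history_htn": history,
        "ethnicity": ethnicity,
        "sbp_mmHg": sbp,
        "dbp_mmHg": dbp,
        "ga_delivery_weeks": delivery,
        "birthweight_centile": centile,
    })
    validate_subjects(subjects)
    return subjects, MeasurementMatrix(values, mask, lod)


def validate_subjects(subjects: pd.DataFrame) -> None:
    """Check the subject-table invariants; raise ``ValueError`` on violation."""
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table lacks columns: {missing}")
    if not subjects["group"].isin(GROUPS).all():
        bad = subjects.loc[~subjects["group"].isin(GROUPS), "group"].unique()
        raise ValueError(f"unknown group labels: {list(bad)}")
    ga = subjects["ga_sampling_days"]
    if ((ga < GA_MIN_DAYS) | (ga > GA_MAX_DAYS)).any():
        raise ValueError("gestational age at sampling outside the 8+0..13+6 week window")
    if (subjects["dbp_mmHg"] > subjects["sbp_mmHg"]).any():
        raise ValueError("diastolic pressure exceeds systolic pressure")
    if (subjects["dbp_mmHg"] <= 0).any():
        raise ValueError("non-positive blood pressure")
    dl = subjects["ga_delivery_weeks"]
    g = subjects["group"]
    if (dl[g == "eo_pe"] >= 34).any():
        raise ValueError("EO-PE subject delivering at or after 34 weeks")
    if (dl[g == "lo_pe"] < 34).any():
        raise ValueError("LO-PE subject delivering before 34 weeks")
    if (dl[g == "control"] < 37).any():
        raise ValueError("control subject delivering before term")


# ---------------------------------------------------------------------------
# outcome generation from a known logistic rule


def generate_from_risk_model(model, covariate_config: dict, n: int,
                             seed: int | None = None) -> pd.DataFrame:
    """Draw covariates and Bernoulli outcomes from a known logistic rule.

    ``covariate_config`` maps every model term either to ``("normal", mean,
    sd)`` or to a callable ``f(rng, n) -> array``.  Returns a table with one
    column per term plus a binary ``outcome`` column.  Used by the
    coefficient-recovery checks of the printed prediction rules.
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    cols = {}
    for term in model.terms:
        if term not in covariate_config:
            raise KeyError(f"covariate_config is missing model term {term!r}")
        spec = covariate_config[term]
        if callable(spec):
            cols[term] = np.asarray(spec(rng, n), float)
        else:
            kind, *params = spec
            if kind != "normal":
                raise ConfigurationError(f"unknown covariate distribution {kind!r}")
            mean, sd = params
            cols[term] = rng.normal(mean, sd, n)
    table = pd.DataFrame(cols, columns=list(model.terms))
    eta = model.intercept + (table.to_numpy() @ np.asarray(model.coefficients)
                             if model.terms else 0.0)
    table["outcome"] = rng.random(n) < expit(eta)
    table["outcome"] = table["outcome"].astype(int)
    return table


# ---------------------------------------------------------------------------
# plain-text fixtures


def write_fixture(subjects: pd.DataFrame, matrix: MeasurementMatrix,
                  path: str | Path) -> None:
    """Write ``subjects.csv``, ``measurements.csv`` and ``analytes.csv``.

    Measurements are wide (subject_id + one column per analyte); an empty
    cell encodes a below-LOD value.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(path / "subjects.csv", index=False)
    wide = matrix.values.rename_axis("subject_id").reset_index()
    # %.17g guarantees exact float round-trip through the text format
    wide.to_csv(path / "measurements.csv", index=False, float_format="%.17g")
    meta = pd.DataFrame({
        "analyte": matrix.analyte_names,
        "lod": [matrix.lod.get(a, np.nan) for a in matrix.analyte_names],
    })
    meta.to_csv(path / "analytes.csv", index=False)


def read_fixture(path: str | Path) -> tuple[pd.DataFrame, MeasurementMatrix]:
    """Read a fixture directory written by :func:`write_fixture`."""
    path = Path(path)
    subjects = pd.read_csv(path / "subjects.csv")
    validate_subjects(subjects)
    wide = pd.read_csv(path / "measurements.csv", float_precision="round_trip")
    if "subject_id" not in wide.columns:
        raise ValueError(f"{path / 'measurements.csv'}: missing subject_id column")
    values = wide.set_index("subject_id")
    neg = values.stack()
    bad = neg[neg <= 0]
    if len(bad):
        subj, analyte = bad.index[0]
        raise ValueError(
            f"{path / 'measurements.csv'}: non-positive concentration "
            f"{bad.iloc[0]!r} at subject {subj!r}, analyte {analyte!r}")
    lod = {}
    meta_path = path / "analytes.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        for _, row in meta.iterrows():
            if np.isfinite(row.get("lod", np.nan)):
                lod[row["analyte"]] = float(row["lod"])
    return subjects, MeasurementMatrix(values, values.isna(), lod)
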