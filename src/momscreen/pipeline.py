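"""End-to-end study replication: simulate/ingest -> preprocess -> split ->
normalize -> select -> fit -> evaluate -> validate, with every stage artifact
written to a run directory.

All randomness is funnelled through two named seeds (generator and split);
re-running a configuration reproduces every output byte-for-byte.  Training
artifacts (median curves, covariate adjustments, marker selection, model
coefficients) are fitted on training-set rows only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design, mom, models as rm, preprocess, selection, synthetic
from .evaluate import (DEFAULT_FPR, ScreeningPerformance, evaluate_scores,
                       select_best_model, subgroup_performance)

__all__ = ["PipelineConfig", "StudyResult", "run_pipeline", "report"]

logger = logging.getLogger(__name__)

MAP_NAME = "MAP"

STAGE_FILES = {
    "simulate": "subjects.csv",
    "preprocess": "preprocess_report.csv",
    "split": "splits.csv",
    "normalize": "mom_table.csv",
    "select": "marker_tests.csv",
    "fit": "models.json",
    "evaluate": "performance.csv",
}


@dataclass(frozen=True)
class PipelineConfig:
    """One config drives the whole run; defaults reproduce the study design."""

    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    input_dir: str | None = None  # read a fixture instead of simulating
    detection_threshold: float = 0.80
    fdr_threshold: float = selection.FDR_THRESHOLD
    fpr: float = DEFAULT_FPR
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    seed_generator: int = 0
    seed_split: int = 1
    outcomes: tuple[str, ...] = ("eo_pe", "lo_pe")
    prior_mode: str = "covariate"  # "covariate" | "offset"
    prior_terms: tuple[str, ...] = rm.PRIOR_TERMS
    adjustment_covariates: tuple[str, ...] = ("weight_kg", "smoking", "ethnicity")
    tie_eps: float = 0.0

    def __post_init__(self):
        for name in ("detection_threshold", "fdr_threshold", "fpr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.prior_mode not in ("covariate", "offset"):
            raise ValueError("prior_mode must be 'covariate' or 'offset'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = raw.pop("generator", {})
        analytes = gen_raw.pop("analytes", None)
        gen_kwargs = dict(gen_raw)
        if analytes is not None:
            gen_kwargs["analytes"] = tuple(synthetic.AnalyteSpec(**a) for a in analytes)
        if "map_spec" in gen_kwargs:
            gen_kwargs["map_spec"] = synthetic.MapSpec(**gen_kwargs["map_spec"])
        if "ga_sampling_range" in gen_kwargs:
            gen_kwargs["ga_sampling_range"] = tuple(gen_kwargs["ga_sampling_range"])
        for key in ("fractions", "outcomes", "prior_terms", "adjustment_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=synthetic.GeneratorConfig(**gen_kwargs), **raw)


@dataclass
class OutcomeResult:
    """Everything the pipeline learns about one outcome (EO-PE or LO-PE)."""

    outcome: str
    marker_tests: list[selection.MarkerTestResult]
    selected: list[str]
    map_selected: bool
    prior_model: rm.RiskModel
    candidate_models: dict[str, rm.RiskModel]
    test_performance: dict[str, ScreeningPerformance]
    best_model_id: str
    validation: ScreeningPerformance
    validation_prior: ScreeningPerformance
    subgroup_sga: ScreeningPerformance | None  # birthweight < 10th centile
    subgroup_aga: ScreeningPerformance | None


@dataclass
class StudyResult:
    config: PipelineConfig
    subjects: pd.DataFrame
    matrix: synthetic.MeasurementMatrix
    splits: design.SplitAssignment
    preprocess_report: preprocess.PreprocessReport
    curves: dict[str, mom.MedianCurve]
    adjustments: dict[str, mom.AdjustmentModel]
    log_mom: pd.DataFrame
    outcomes: dict[str, OutcomeResult]


# ---------------------------------------------------------------------------
# stage helpers


def _append_map(subjects: pd.DataFrame,
                matrix: synthetic.MeasurementMatrix) -> synthetic.MeasurementMatrix:
    """Add MAP (from the blood pressures) as one more, always-detected marker."""
    map_vals = preprocess.compute_map(subjects["sbp_mmHg"], subjects["dbp_mmHg"])
    values = matrix.values.copy()
    values[MAP_NAME] = pd.Series(np.asarray(map_vals),
                                 index=subjects["subject_id"]).loc[values.index]
    mask = matrix.below_lod_mask.copy()
    mask[MAP_NAME] = False
    return synthetic.MeasurementMatrix(values, mask, dict(matrix.lod))


def _design_for_terms(terms: tuple[str, ...], log_mom: pd.DataFrame,
                      prior_lo: pd.Series, ids) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Design matrix for a candidate model on the given subjects.

    ``prior`` -> prior log-odds, ``MAP`` -> MAP on the MoM scale, any other
    term -> that marker's log10 MoM.  Returns (design, offset) where offset is
    non-None only in offset mode (terms then exclude ``prior``).
    """
    cols = {}
    for t in terms:
        if t == "prior":
            cols[t] = prior_lo.loc[ids].to_numpy()
        elif t == MAP_NAME:
            cols[t] = 10.0 ** log_mom.loc[ids, MAP_NAME].to_numpy()
        else:
            cols[t] = log_mom.loc[ids, t].to_numpy()
    return pd.DataFrame(cols, index=ids), None


def _score(model: rm.RiskModel, log_mom: pd.DataFrame, prior_lo: pd.Series,
           ids, offset_prior: bool) -> np.ndarray:
    X, _ = _design_for_terms(model.terms, log_mom, prior_lo, ids)
    eta = model.intercept + X.to_numpy() @ np.asarray(model.coefficients)
    if offset_prior:
        eta = eta + prior_lo.loc[ids].to_numpy()
    from scipy.special import expit
    return expit(eta)


def _run_outcome(cfg: PipelineConfig, outcome: str, subjects: pd.DataFrame,
                 log_mom: pd.DataFrame, splits: design.SplitAssignment,
                 ) -> OutcomeResult:
    subj = subjects.set_index("subject_id")
    train_ids = splits.subjects_in("train")
    relevant = subj["group"].isin(["control", outcome])

    def ids_of(which):
        ids = splits.subjects_in(which)
        return ids[relevant.loc[ids]]

    # marker pre-selection on the training set
    tests = selection.test_markers(log_mom, subjects, outcome,
                                   subject_ids=train_ids,
                                   q_threshold=cfg.fdr_threshold)
    hits = selection.select_markers(tests, cfg.fdr_threshold)
    map_selected = any(r.marker == MAP_NAME for r in hits)
    selected = [r.marker for r in hits if r.marker != MAP_NAME]

    # prior-risk model on the training set
    prior_model, _ = rm.fit_prior_risk(subjects[subjects["subject_id"].isin(train_ids)],
                                       outcome, cfg.prior_terms)
    all_ids = subj.index[relevant]
    prior_lo = pd.Series(
        rm.prior_logodds(rm.predict_risk(prior_model, subj.loc[all_ids])),
        index=all_ids)

    offset_mode = cfg.prior_mode == "offset"
    candidates: dict[str, rm.RiskModel] = {}
    perfs: dict[str, ScreeningPerformance] = {}
    tr = ids_of("train")
    te = ids_of("test")
    y_train = (subj.loc[tr, "group"] == outcome).to_numpy(int)
    groups_te = subj.loc[te, "group"]
    for terms in rm.enumerate_candidate_models(selected, map_selected):
        fit_terms = tuple(t for t in terms if t != "prior") if offset_mode else terms
        mid = rm.model_id(terms)
        X, _ = _design_for_terms(fit_terms, log_mom, prior_lo, tr)
        offset = prior_lo.loc[tr].to_numpy() if offset_mode else None
        try:
            model = rm.fit_combined_model(X, y_train, outcome, fit_terms,
                                          offset=offset, meta={"model_id": mid})
        except rm.FitError as exc:
            logger.warning("skipping candidate %s: %s", mid, exc)
            continue
        candidates[mid] = model
        scores = pd.Series(_score(model, log_mom, prior_lo, te, offset_mode),
                           index=te)
        perfs[mid] = evaluate_scores(scores[groups_te == outcome],
                                     scores[groups_te == "control"],
                                     model=mid, dataset="test", fpr=cfg.fpr,
                                     n_terms=len(terms))
    best = select_best_model(list(perfs.values()), cfg.tie_eps)

    # validation on never-before-seen subjects
    va = ids_of("validation")
    groups_va = subj.loc[va, "group"]
    centile_va = subj.loc[va, "birthweight_centile"]

    def _validate(mid: str) -> ScreeningPerformance:
        scores = pd.Series(_score(candidates[mid], log_mom, prior_lo, va, offset_mode),
                           index=va)
        return evaluate_scores(scores[groups_va == outcome],
                               scores[groups_va == "control"],
                               model=mid, dataset="validation", fpr=cfg.fpr,
                               n_terms=len(candidates[mid].terms))

    validation = _validate(best.model)
    validation_prior = _validate(rm.model_id(("prior",)))
    scores_va = pd.Series(_score(candidates[best.model], log_mom, prior_lo, va,
                                 offset_mode), index=va)
    case_scores = scores_va[groups_va == outcome]
    ctrl_scores = scores_va[groups_va == "control"]
    case_centile = centile_va[groups_va == outcome].to_numpy()
    sga = subgroup_performance(case_scores, ctrl_scores, case_centile < 10,
                               model=best.model, dataset="validation_sga",
                               fpr=cfg.fpr)
    aga = subgroup_performance(case_scores, ctrl_scores, case_centile >= 10,
                               model=best.model, dataset="validation_aga",
                               fpr=cfg.fpr)
    return OutcomeResult(outcome, tests, selected, map_selected, prior_model,
                         candidates, perfs, best.model, validation,
                         validation_prior, sga, aga)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full analysis; optionally write every stage artifact.

    Stages: simulate (or ingest) -> MAP + detection filter + imputation ->
    split -> median curves + MoM + covariate adjustment -> t-test/FDR marker
    selection -> candidate logistic models -> test-set evaluation and
    selection -> validation and birthweight-centile subgroups.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        subjects, raw = synthetic.read_fixture(config.input_dir)
        logger.info("ingest: %d subjects, %d analytes from %s",
                    len(subjects), len(raw.analyte_names), config.input_dir)
    else:
        subjects, raw = synthetic.generate_cohort(config.generator,
                                                  config.seed_generator)
        logger.info("simulate: %d subjects, %d analytes (seed %d)",
                    len(subjects), len(raw.analyte_names), config.seed_generator)
    if out is not None:
        synthetic.write_fixture(subjects, raw, out)

    filtered, prep = preprocess.apply_detection_filter(raw,
                                                       config.detection_threshold)
    matrix = preprocess.impute_below_lod(filtered, prep)
    matrix = _append_map(subjects, matrix)
    logger.info("preprocess: %d of %d analytes retained (+ MAP)",
                prep.analytes_retained, prep.analytes_in)

    splits = design.assign_splits(subjects, config.fractions, config.seed_split)
    train_ids = splits.subjects_in("train")
    train_controls = subjects[subjects["subject_id"].isin(train_ids)
                              & (subjects["group"] == "control")]
    logger.info("split: %s", {g: c for g, c in splits.group_counts.items()})

    curves = mom.fit_median_curves(subjects, matrix, train_controls["subject_id"])
    raw_log_mom = mom.compute_log_mom_table(matrix, subjects, curves)
    adjustments = mom.fit_adjustment(train_controls, raw_log_mom,
                                     config.adjustment_covariates)
    log_mom = mom.apply_adjustment(raw_log_mom, adjustments, subjects)
    n_adj = sum(not m.is_identity for m in adjustments.values())
    logger.info("normalize: %d markers, %d with covariate adjustment",
                log_mom.shape[1], n_adj)

    outcomes = {}
    for outcome in config.outcomes:
        res = _run_outcome(config, outcome, subjects, log_mom, splits)
        logger.info("%s: selected %s%s; best model %r (test DR %.2f)",
                    outcome, res.selected,
                    " + MAP" if res.map_selected else "",
                    res.best_model_id,
                    res.test_performance[res.best_model_id].dr_at_fpr)
        outcomes[outcome] = res

    result = StudyResult(config, subjects, raw, splits, prep, curves,
                         adjustments, log_mom, outcomes)
    if out is not None:
        _write_artifacts(result, out)
    return result


def _perf_row(p: ScreeningPerformance, outcome: str) -> dict:
    return {"outcome": outcome, "model": p.model, "dataset": p.dataset,
            "dr_at_fpr": p.dr_at_fpr, "fpr": p.fpr,
            "dr_ci_low": p.dr_ci[0], "dr_ci_high": p.dr_ci[1], "auc": p.auc,
            "threshold": p.threshold, "n_cases": p.n_cases,
            "n_controls": p.n_controls}


def _write_artifacts(result: StudyResult, out: Path) -> None:
    result.splits.to_frame().to_csv(out / "splits.csv", index=False)
    result.preprocess_report.to_frame().to_csv(out / "preprocess_report.csv",
                                               index=False)
    pd.DataFrame([{"analyte": c.analyte, "intercept": c.intercept,
                   "slope": c.slope} for c in result.curves.values()]
                 ).to_csv(out / "median_curves.csv", index=False)
    result.log_mom.rename_axis("subject_id").to_csv(out / "mom_table.csv")
    adj_rows = []
    for m in result.adjustments.values():
        for name, coef in m.coefficients.items():
            adj_rows.append({"marker": m.marker, "term": name, "coefficient": coef,
                             "center": m.centers[name]})
    pd.DataFrame(adj_rows, columns=["marker", "term", "coefficient", "center"]
                 ).to_csv(out / "adjustments.csv", index=False)

    tests = pd.concat([selection.results_to_frame(o.marker_tests)
                       for o in result.outcomes.values()], ignore_index=True)
    tests.to_csv(out / "marker_tests.csv", index=False)

    all_models, perf_rows, summary = [], [], {}
    for outcome, o in result.outcomes.items():
        all_models.append(dataclasses.replace(
            o.prior_model, meta={**o.prior_model.meta, "model_id": "prior(raw)"}))
        all_models.extend(o.candidate_models.values())
        for p in o.test_performance.values():
            perf_rows.append(_perf_row(p, outcome))
        perf_rows.append(_perf_row(o.validation, outcome))
        perf_rows.append(_perf_row(o.validation_prior, outcome))
        for sub in (o.subgroup_sga, o.subgroup_aga):
            if sub is not None:
                perf_rows.append(_perf_row(sub, outcome))
        summary[outcome] = {
            "selected_markers": o.selected, "map_selected": o.map_selected,
            "best_model": o.best_model_id,
            "test_dr": o.test_performance[o.best_model_id].dr_at_fpr,
            "validation_dr": o.validation.dr_at_fpr,
            "validation_prior_dr": o.validation_prior.dr_at_fpr,
        }
    rm.save_models(all_models, out / "models.json")
    pd.DataFrame(perf_rows).to_csv(out / "performance.csv", index=False)
    summary["seeds"] = {"generator": result.config.seed_generator,
                        "split": result.config.seed_split}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "report.txt").write_text(report(out))


# ---------------------------------------------------------------------------
# reporting


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory.

    Renders the marker-selection table and the screening-performance table;
    an incomplete run is reported with its missing stages listed.
    """
    run = Path(run_dir)
    missing = [stage for stage, fname in STAGE_FILES.items()
               if not (run / fname).exists()]
    lines = ["momscreen run report"]
    if (run / "summary.json").exists():
        summary = json.loads((run / "summary.json").read_text())
        seeds = summary.pop("seeds", {})
        lines.append(f"seeds: generator={seeds.get('generator')} "
                     f"split={seeds.get('split')}")
    if missing:
        lines.append(f"INCOMPLETE RUN - missing stages: {', '.join(missing)}")
        return "\n".join(lines) + "\n"

    tests = pd.read_csv(run / "marker_tests.csv")
    sel = tests[tests["selected"]].sort_values(["outcome", "fdr_q"])
    lines += ["", "Markers selected (t-test on log10 MoMs, FDR < 15%):",
              "outcome   marker          p-value    FDR      MoM ratio"]
    if sel.empty:
        lines.append("  (none)")
    for _, r in sel.iterrows():
        lines.append(f"{r['outcome']:<9} {r['marker']:<15} "
                     f"{r['p_value']:<10.2g} {r['fdr_q']:<8.2g} {r['mom_ratio']:.2f}")

    perf = pd.read_csv(run / "performance.csv")
    lines += ["", f"Screening performance (DR at {perf['fpr'].iloc[0]:.0%} FPR):",
              "outcome   dataset          model                          "
              "DR (95% CI)        AUC"]
    for _, r in perf.iterrows():
        ci = f"{r['dr_at_fpr']:.0%} ({r['dr_ci_low']:.0%}-{r['dr_ci_high']:.0%})"
        lines.append(f"{r['outcome']:<9} {r['dataset']:<16} {r['model']:<30} "
                     f"{ci:<18} {r['auc']:.2f}")
    return "\n".join(lines) + "\n"
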