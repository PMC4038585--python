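"""Logistic risk models: prior risk from maternal characteristics and
combined models adding MAP MoM and selected marker log10 MoMs.

The prior-risk model is a maximum-likelihood logistic regression of the
outcome on maternal characteristics (nulliparity, weight, history of
hypertensive pregnancy disorders, smoking), fitted on the training set only.
Combined models add marker terms; the prior risk enters either as its
log-odds used as one covariate (default) or as a fixed offset — the two modes
exist because published screening rules often print only the marker terms,
leaving the prior's incorporation ambiguous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "PRIOR_TERMS",
    "fit_prior_risk",
    "fit_combined_model",
    "predict_risk",
    "enumerate_candidate_models",
    "model_id",
    "save_models",
    "load_models",
]

#: default maternal-characteristic terms of the prior-risk model
PRIOR_TERMS = ("nulliparous", "weight_kg", "history_htn", "smoking")


class FitError(RuntimeError):
    """Logistic fit failed (separation, collinearity or non-convergence)."""


@dataclass(frozen=True)
class RiskModel:
    """A fitted logistic prediction rule: ``risk = expit(b0 + sum b_i x_i)``."""

    outcome: str
    terms: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.terms) != len(self.coefficients):
            raise ValueError("terms and coefficients differ in length")

    def coefficient(self, term: str) -> float:
        try:
            return self.coefficients[self.terms.index(term)]
        except ValueError:
            raise KeyError(f"model has no term {term!r}") from None

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "terms": list(self.terms),
                "intercept": self.intercept,
                "coefficients": list(self.coefficients), "meta": self.meta}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(d["outcome"], tuple(d["terms"]), float(d["intercept"]),
                   tuple(float(c) for c in d["coefficients"]), dict(d.get("meta", {})))


def predict_risk(model: RiskModel, covariates) -> np.ndarray | float:
    """Predicted probability for a mapping/DataFrame of covariate values.

    Every model term must be supplied; a missing one raises naming it.
    """
    if isinstance(covariates, pd.DataFrame):
        get = lambda t: covariates[t].to_numpy(float) if t in covariates else None
    else:
        get = lambda t: covariates.get(t)
    eta = model.intercept
    for term, coef in zip(model.terms, model.coefficients):
        val = get(term)
        if val is None:
            raise KeyError(f"missing covariate for model term {term!r}")
        eta = eta + coef * np.asarray(val, float)
    out = expit(eta)
    return float(out) if np.ndim(out) == 0 else out


def _ml_logistic(X: np.ndarray, y: np.ndarray, names: list[str],
                 offset: np.ndarray | None = None):
    """Plain ML logistic fit; raises :class:`FitError` on degeneracy."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError(f"collinear design over terms {names}")
    try:
        res = sm.Logit(y, design, offset=offset).fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:  # perfect separation, singular Hessian, ...
        raise FitError(f"logistic fit failed for terms {names}: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError(f"logistic fit did not converge for terms {names}")
    return res


def fit_prior_risk(training_subjects: pd.DataFrame, outcome: str,
                   terms: tuple[str, ...] = PRIOR_TERMS,
                   ) -> tuple[RiskModel, pd.Series]:
    """Fit the prior-risk logistic model on training cases vs training controls.

    Returns the model and the per-subject prior risk for the training rows
    used (indexed by subject_id).  Needs >= 10 cases and >= 10 controls.
    """
    subj = training_subjects.set_index("subject_id")
    keep = subj["group"].isin(["control", outcome])
    subj = subj.loc[keep]
    y = (subj["group"] == outcome).to_numpy(int)
    if y.sum() < 10 or (1 - y).sum() < 10:
        raise ValueError(f"need >= 10 {outcome} cases and >= 10 controls "
                         f"(got {y.sum()} / {(1 - y).sum()})")
    # a binary characteristic with an empty outcome-by-level cell has an
    # infinite MLE (quasi-separation); drop it rather than diverge
    dropped = []
    kept_terms = []
    for t in terms:
        col = subj[t].astype(float).to_numpy()
        if set(np.unique(col)) <= {0.0, 1.0}:
            cells = [(y[col == v] == o).sum() for v in (0, 1) for o in (0, 1)]
            if 0 in cells:
                dropped.append(t)
                logger.warning("prior-risk term %r has an empty outcome cell "
                               "in the training set; dropped", t)
                continue
        kept_terms.append(t)
    terms = tuple(kept_terms)
    X = subj[list(terms)].astype(float).to_numpy()
    res = _ml_logistic(X, y, list(terms))
    model = RiskModel(outcome, tuple(terms), float(res.params[0]),
                      tuple(res.params[1:]),
                      meta={"kind": "prior_risk", "n_cases": int(y.sum()),
                            "n_controls": int((1 - y).sum()),
                            "dropped_terms": dropped})
    prior = pd.Series(predict_risk(model, subj), index=subj.index, name="prior_risk")
    return model, prior


def fit_combined_model(design: pd.DataFrame, y, outcome: str,
                       terms: tuple[str, ...] | None = None,
                       offset=None, meta: dict | None = None) -> RiskModel:
    """ML logistic fit of a binary outcome on the given term columns.

    ``design`` holds one column per term (e.g. prior log-odds, MAP MoM,
    marker log10 MoMs); ``offset`` (optional) is added to the linear predictor
    with coefficient fixed at 1, the "offset" mode of prior-risk handling.
    """
    terms = tuple(terms if terms is not None else design.columns)
    missing = [t for t in terms if t not in design.columns]
    if missing:
        raise KeyError(f"design lacks term columns {missing}")
    y = np.asarray(y, int)
    X = design[list(terms)].astype(float).to_numpy()
    off = None if offset is None else np.asarray(offset, float)
    res = _ml_logistic(X, y, list(terms), offset=off)
    m = {"kind": "combined", "n_cases": int(y.sum()),
         "n_controls": int(len(y) - y.sum()), "offset_mode": offset is not None}
    m.update(meta or {})
    return RiskModel(outcome, terms, float(res.params[0]), tuple(res.params[1:]),
                     meta=m)


def prior_logodds(prior_risk) -> np.ndarray:
    """Log-odds of a prior-risk probability, the default covariate form."""
    p = np.asarray(prior_risk, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("prior risks must lie strictly in (0, 1)")
    return logit(p)


def enumerate_candidate_models(selected_markers: list[str],
                               map_selected: bool) -> list[tuple[str, ...]]:
    """All candidate term sets: prior risk plus every subset of the selected
    markers (with MAP included among the candidates only if it passed the
    FDR gate).  The empty subset is the prior-risk-only model."""
    pool = (["MAP"] if map_selected else []) + [m for m in selected_markers
                                               if m != "MAP"]
    out: list[tuple[str, ...]] = []
    for bits in range(2 ** len(pool)):
        subset = tuple(pool[i] for i in range(len(pool)) if bits >> i & 1)
        out.append(("prior",) + subset)
    out.sort(key=lambda t: (len(t), t))
    return out


def model_id(terms: tuple[str, ...]) -> str:
    return " + ".join(terms)


def save_models(models: list[RiskModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=2))


def load_models(path: str | Path) -> list[RiskModel]:
    return [RiskModel.from_dict(d) for d in json.loads(Path(path).read_text())]
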