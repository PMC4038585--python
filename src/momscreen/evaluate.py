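"""Screening performance: detection rate at a fixed false-positive rate.

A screening model is summarised by the detection rate (DR, sensitivity) it
achieves when the risk cutoff is set so that a fixed fraction of unaffected
pregnancies screen positive (the false-positive rate, FPR, fixed at 10%
here).  The cutoff is the empirical (1 - FPR) quantile of the control scores
(inverse empirical CDF), and a subject screens positive when her score is
strictly above it.  The AUC is the Mann–Whitney probability that a random
case outscores a random control (ties counted 1/2); DR confidence intervals
are Wilson score intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ScreeningPerformance",
    "dr_at_fpr",
    "dr_confidence_interval",
    "auc",
    "evaluate_scores",
    "select_best_model",
    "subgroup_performance",
    "roc_points",
]

DEFAULT_FPR = 0.10


@dataclass(frozen=True)
class ScreeningPerformance:
    """DR at fixed FPR with its 95% CI, AUC and the risk cutoff used."""

    model: str
    dataset: str
    dr_at_fpr: float
    fpr: float
    dr_ci: tuple[float, float]
    auc: float
    threshold: float
    n_cases: int
    n_controls: int
    n_terms: int = 0

    def __post_init__(self):
        lo, hi = self.dr_ci
        if not (0.0 <= lo <= self.dr_at_fpr <= hi <= 1.0):
            raise ValueError("CI must contain the detection rate within [0, 1]")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")

    @property
    def empty(self) -> bool:
        return self.n_cases == 0


def dr_at_fpr(case_scores, control_scores, fpr: float = DEFAULT_FPR,
              ) -> tuple[float, float]:
    """Detection rate at a fixed FPR; returns ``(dr, threshold)``.

    The threshold is the (1 - fpr) empirical quantile of the control scores
    under the inverse-ECDF convention (the ``ceil((1-fpr)*n)``-th control
    order statistic); subjects score positive by strict ``>``.  ``fpr >= 1``
    puts the threshold below every score so every case is detected.
    """
    case = np.asarray(case_scores, float)
    ctrl = np.asarray(control_scores, float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both score groups must be nonempty")
    if not 0.0 < fpr <= 1.0:
        raise ValueError("fpr must lie in (0, 1]")
    k = math.ceil((1.0 - fpr) * ctrl.size)
    threshold = -np.inf if k == 0 else float(np.sort(ctrl)[k - 1])
    dr = float(np.mean(case > threshold))
    return dr, threshold


def dr_confidence_interval(k: int, n: int, level: float = 0.95,
                           ) -> tuple[float, float]:
    """Wilson score interval for ``k`` detected of ``n`` cases."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def auc(case_scores, control_scores) -> float:
    """Mann–Whitney AUC: P(case score > control score) + P(tie)/2."""
    case = np.asarray(case_scores, float)
    ctrl = np.asarray(control_scores, float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both score groups must be nonempty")
    ranks = rankdata(np.concatenate([case, ctrl]))
    u = ranks[:case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * ctrl.size))


def evaluate_scores(case_scores, control_scores, model: str = "", dataset: str = "",
                    fpr: float = DEFAULT_FPR, n_terms: int = 0,
                    ) -> ScreeningPerformance:
    """Full screening summary of one model's scores on one dataset."""
    case = np.asarray(case_scores, float)
    ctrl = np.asarray(control_scores, float)
    dr, thr = dr_at_fpr(case, ctrl, fpr)
    k = int(round(dr * case.size))
    return ScreeningPerformance(
        model=model, dataset=dataset, dr_at_fpr=dr, fpr=fpr,
        dr_ci=dr_confidence_interval(k, case.size), auc=auc(case, ctrl),
        threshold=thr, n_cases=case.size, n_controls=ctrl.size, n_terms=n_terms)


def select_best_model(performances: list[ScreeningPerformance],
                      tie_eps: float = 0.0) -> ScreeningPerformance:
    """Highest test-set DR; ties (within ``tie_eps``) go to the model with
    the fewest terms — the parsimony rule that discards a larger model
    offering no DR improvement."""
    if not performances:
        raise ValueError("no candidate models to select from")
    best_dr = max(p.dr_at_fpr for p in performances)
    contenders = [p for p in performances if p.dr_at_fpr >= best_dr - tie_eps]
    return min(contenders, key=lambda p: (p.n_terms, -p.dr_at_fpr, p.model))


def subgroup_performance(case_scores, control_scores, case_in_subgroup,
                         model: str = "", dataset: str = "",
                         fpr: float = DEFAULT_FPR) -> ScreeningPerformance | None:
    """Performance on the case subset selected by ``case_in_subgroup``
    (e.g. birthweight below the 10th centile), against all controls.

    Returns ``None`` when no case falls in the subgroup."""
    keep = np.asarray(case_in_subgroup, bool)
    case = np.asarray(case_scores, float)
    if keep.shape != case.shape:
        raise ValueError("subgroup mask must align with case scores")
    if not keep.any():
        return None
    return evaluate_scores(case[keep], control_scores, model=model,
                           dataset=dataset, fpr=fpr)


def roc_points(case_scores, control_scores) -> pd.DataFrame:
    """Empirical ROC curve: (FPR, TPR) at every distinct score cutoff."""
    case = np.asarray(case_scores, float)
    ctrl = np.asarray(control_scores, float)
    cuts = np.unique(np.concatenate([case, ctrl]))
    rows = [(1.0, 1.0)]
    for c in cuts:
        rows.append((float(np.mean(ctrl > c)), float(np.mean(case > c))))
    df = pd.DataFrame(rows, columns=["fpr", "tpr"]).drop_duplicates()
    return df.sort_values(["fpr", "tpr"]).reset_index(drop=True)
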