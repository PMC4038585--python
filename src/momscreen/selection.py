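"""Marker pre-selection: per-marker t-tests on log MoMs with FDR control.

Each retained marker (plus MAP) is compared between cases and training-set
controls by a two-sided Student's t-test on log10 MoMs; p-values are corrected
per outcome across the whole tested panel by the Benjamini–Hochberg step-up,
and markers with FDR strictly below 15% pass the gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mom import mom_ratio

__all__ = [
    "MarkerTestResult",
    "t_test_log_mom",
    "bh_fdr",
    "test_markers",
    "select_markers",
    "FDR_THRESHOLD",
]

FDR_THRESHOLD = 0.15


@dataclass(frozen=True)
class MarkerTestResult:
    marker: str
    outcome: str  # "eo_pe" | "lo_pe"
    t_statistic: float
    p_value: float
    fdr_q: float
    momr: float
    selected: bool


def t_test_log_mom(case_values, control_values, equal_var: bool = True,
                   ) -> tuple[float, float]:
    """Two-sided two-sample t-test on log10 MoMs (pooled variance by default).

    ``equal_var=False`` gives the Welch variant.  Degenerate (zero pooled
    variance) inputs raise rather than returning NaN.
    """
    case = np.asarray(case_values, float)
    ctrl = np.asarray(control_values, float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(case) == 0 and np.var(ctrl) == 0:
        raise ValueError("zero variance in both groups; t-test undefined")
    res = stats.ttest_ind(case, ctrl, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values, capped at
    1.  Monotone non-decreasing in p by construction.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_markers(log_mom_table: pd.DataFrame, subjects: pd.DataFrame, outcome: str,
                 subject_ids=None, q_threshold: float = FDR_THRESHOLD,
                 equal_var: bool = True) -> list[MarkerTestResult]:
    """Test every marker of the table for ``outcome`` cases vs controls.

    ``subject_ids`` restricts the comparison (normally to the training set).
    FDR correction is applied across all tested markers jointly for this
    outcome.  MoM ratios are computed on the MoM scale from the same log10
    MoMs.
    """
    if outcome not in ("eo_pe", "lo_pe"):
        raise ValueError(f"unknown outcome {outcome!r}")
    subj = subjects.set_index("subject_id")
    if subject_ids is not None:
        subj = subj.loc[pd.Index(subject_ids).intersection(subj.index)]
    table = log_mom_table.loc[log_mom_table.index.intersection(subj.index)]
    subj = subj.loc[table.index]
    case_ids = subj.index[subj["group"] == outcome]
    ctrl_ids = subj.index[subj["group"] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(f"too few {outcome} cases or controls to test")

    stats_rows = []
    for marker in table.columns:
        t, p = t_test_log_mom(table.loc[case_ids, marker], table.loc[ctrl_ids, marker],
                              equal_var=equal_var)
        r = mom_ratio(10.0 ** table.loc[case_ids, marker].to_numpy(),
                      10.0 ** table.loc[ctrl_ids, marker].to_numpy())
        stats_rows.append((marker, t, p, r))
    q = bh_fdr([p for _, _, p, _ in stats_rows])
    return [MarkerTestResult(marker, outcome, t, p, float(qi), r, bool(qi < q_threshold))
            for (marker, t, p, r), qi in zip(stats_rows, q)]


def select_markers(results: list[MarkerTestResult],
                   q_threshold: float = FDR_THRESHOLD) -> list[MarkerTestResult]:
    """Markers with FDR strictly below the threshold, ordered by q ascending."""
    hits = [r for r in results if r.fdr_q < q_threshold]
    return sorted(hits, key=lambda r: (r.fdr_q, r.p_value, r.marker))


def results_to_frame(results: list[MarkerTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "marker": r.marker, "outcome": r.outcome, "t": r.t_statistic,
        "p_value": r.p_value, "fdr_q": r.fdr_q, "mom_ratio": r.momr,
        "selected": r.selected,
    } for r in results])
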