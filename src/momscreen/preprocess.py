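"""Detection-rate filtering, below-LOD imputation, and mean arterial pressure.

Only analytes detected in more than 80% of samples enter the analysis; the
remaining below-LOD cells of retained analytes are imputed as half the lowest
detected value of that analyte — a compromise between substituting zero
(underestimate) and truncating at the LOD (overestimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import MeasurementMatrix

__all__ = [
    "PreprocessReport",
    "compute_map",
    "detection_fraction",
    "apply_detection_filter",
    "impute_below_lod",
]


@dataclass
class PreprocessReport:
    """Bookkeeping of the detection filter and imputation steps."""

    analytes_in: int
    analytes_retained: int
    threshold: float
    detection: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    imputation_values: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, frac in self.detection.items():
            rows.append({
                "analyte": name,
                "detection_fraction": frac,
                "retained": name not in self.dropped,
                "imputation_value": self.imputation_values.get(name, np.nan),
            })
        return pd.DataFrame(rows)


def compute_map(sbp, dbp):
    """Mean arterial pressure: ``DBP + (SBP - DBP)/3`` (mmHg).

    Accepts scalars or arrays; requires ``0 < DBP <= SBP``.
    """
    sbp = np.asarray(sbp, float)
    dbp = np.asarray(dbp, float)
    if np.any(dbp <= 0) or np.any(sbp <= 0):
        raise ValueError("blood pressures must be positive")
    if np.any(dbp > sbp):
        raise ValueError("diastolic pressure exceeds systolic pressure")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def detection_fraction(matrix: MeasurementMatrix, analyte: str) -> float:
    """Fraction of subjects with a detected (above-LOD) value for ``analyte``."""
    if analyte not in matrix.values.columns:
        raise KeyError(f"unknown analyte {analyte!r}")
    mask = matrix.below_lod_mask[analyte]
    return float((~mask).sum() / len(mask))


def apply_detection_filter(matrix: MeasurementMatrix, threshold: float = 0.80,
                           ) -> tuple[MeasurementMatrix, PreprocessReport]:
    """Retain analytes detected in strictly more than ``threshold`` of samples.

    The fraction is computed over all subjects pooled (all groups and splits);
    an analyte detected in exactly ``threshold`` of samples is dropped.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("detection threshold must be in (0, 1)")
    det = {a: detection_fraction(matrix, a) for a in matrix.analyte_names}
    retained = [a for a in matrix.analyte_names if det[a] > threshold]
    dropped = [a for a in matrix.analyte_names if a not in retained]
    report = PreprocessReport(
        analytes_in=len(det), analytes_retained=len(retained),
        threshold=threshold, detection=det, dropped=dropped)
    return matrix.select_analytes(retained), report


def impute_below_lod(matrix: MeasurementMatrix,
                     report: PreprocessReport | None = None) -> MeasurementMatrix:
    """Replace each below-LOD cell by half the lowest detected value of its analyte.

    Detected values are untouched and the mask is cleared; idempotent.  An
    analyte with no detected value at all has no defined lowest detectable
    value and raises.
    """
    values = matrix.values.copy()
    for analyte in matrix.analyte_names:
        col = values[analyte]
        masked = matrix.below_lod_mask[analyte]
        if not masked.any():
            continue
        detected = col[~masked]
        if detected.empty:
            raise ValueError(
                f"analyte {analyte!r} has no detected values; "
                "cannot impute half the lowest detectable value")
        fill = float(detected.min()) / 2.0
        values.loc[masked, analyte] = fill
        if report is not None:
            report.imputation_values[analyte] = fill
    cleared = pd.DataFrame(False, index=values.index, columns=values.columns)
    return MeasurementMatrix(values, cleared, dict(matrix.lod))
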