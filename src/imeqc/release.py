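"""Encapsulation efficiency, internal-standard calibration, and
replacement-corrected cumulative dialysis release.

In a sample-and-replace dialysis assay, each aliquot permanently removes
drug from the reservoir and is replaced with drug-free buffer, so the
measured concentration at any time undercounts the total released mass.
The mass-balance correction adds back every previously removed aliquot:

    M_cum(t_i) = C_i * V_reservoir + sum_{j<i} C_j * V_aliquot

The naive (uncorrected) estimate C_i * V_reservoir is also emitted for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReleaseSeries", "CalibrationCurve", "encapsulation_efficiency",
           "fit_calibration", "invert_calibration", "cumulative_release"]


@dataclass
class ReleaseSeries:
    times_h: np.ndarray
    conc_mg_per_ml: np.ndarray
    v_reservoir_ml: float = 14.0
    v_aliquot_ml: float = 1.0
    loaded_mass_mg: float | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=np.float64)
        self.conc_mg_per_ml = np.asarray(self.conc_mg_per_ml, dtype=np.float64)
        if self.times_h.shape != self.conc_mg_per_ml.shape:
            raise ValueError("times and concentrations must align")
        if self.times_h.size > 1 and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc_mg_per_ml < 0):
            raise ValueError("concentrations must be >= 0")
        if self.v_aliquot_ml > self.v_reservoir_ml:
            raise ValueError("aliquot volume cannot exceed the reservoir")


@dataclass
class CalibrationCurve:
    """OLS line of analyte/internal-standard peak-area ratio on
    concentration ratio."""

    slope: float
    intercept: float
    residuals: np.ndarray


def encapsulation_efficiency(total_mg: float, unencapsulated_mg: float) -> float:
    """EE(%) = (total used drug - unencapsulated drug) / total x 100."""
    if total_mg <= 0:
        raise ValueError("total drug mass must be positive")
    if not (0 <= unencapsulated_mg <= total_mg):
        raise ValueError("unencapsulated mass must lie in [0, total]")
    return (total_mg - unencapsulated_mg) / total_mg * 100.0


def fit_calibration(conc_ratios, area_ratios) -> CalibrationCurve:
    """Least-squares calibration line: area ratio = slope * conc ratio +
    intercept. Needs >= 2 distinct concentration ratios."""
    x = np.asarray(conc_ratios, dtype=np.float64)
    y = np.asarray(area_ratios, dtype=np.float64)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct concentration ratios")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            residuals=resid)


def invert_calibration(curve: CalibrationCurve, area_ratio: float) -> float:
    """Unknown concentration ratio from a measured peak-area ratio."""
    if curve.slope == 0:
        raise ValueError("cannot invert a flat calibration curve")
    return (area_ratio - curve.intercept) / curve.slope


def cumulative_release(series: ReleaseSeries,
                       mass_tolerance: float = 1e-6) -> pd.DataFrame:
    """Replacement-corrected cumulative released mass per sample time.

    Columns: cumulative mass (corrected and naive), and — when
    loaded_mass_mg is known — the released fraction plus a monotonicity
    flag (violations are flagged, never silently repaired). A corrected
    fraction exceeding 1 + tolerance means the mass balance is broken and
    raises.
    """
    C = series.conc_mg_per_ml
    v_res, v_al = series.v_reservoir_ml, series.v_aliquot_ml
    removed_before = np.concatenate(([0.0], np.cumsum(C[:-1] * v_al)))
    m_cum = C * v_res + removed_before
    out = pd.DataFrame({
        "time_h": series.times_h,
        "cumulative_mg": m_cum,
        "cumulative_mg_naive": C * v_res,
    })
    out["monotone"] = np.concatenate(([True], np.diff(m_cum) >= 0))
    if series.loaded_mass_mg is not None:
        frac = m_cum / series.loaded_mass_mg
        if np.any(frac > 1.0 + mass_tolerance):
            raise ValueError("cumulative release exceeds loaded mass: "
                             f"max fraction {frac.max():.6f}")
        out["fraction_released"] = frac
    return out
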