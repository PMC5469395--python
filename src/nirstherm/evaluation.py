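"""Prediction-quality metrics and regression ROC (RROC) analysis.

A temperature prediction is scored by R^2 (squared Pearson correlation by
default -- anchored predictions may carry a level offset that the
1 - SS_res/SS_tot definition would punish), MAE, MSE and the mean error bias
MEB = mean(predicted - measured); positive MEB means the predicted tissue
temperature overestimates the reference.

The RROC curve sweeps a constant shift s over the predictions and plots
total over-estimation OVER(s) = sum(max(e_i + s, 0)) against total
under-estimation UNDER(s) = sum(min(e_i + s, 0)). Both totals are reported
*per sample* (divided by n) so subjects with different recording lengths
share one plot. The area over the curve (AOC) behaves as an error-variance
surrogate; a curve dominates another when it is everywhere above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "MetricsReport",
    "RROCCurve",
    "prediction_metrics",
    "rroc_curve",
    "dominance",
    "metric_correlations",
]

METRIC_NAMES = ("mae", "mse", "aoc", "meb")


@dataclass(frozen=True)
class MetricsReport:
    """Per-subject scalar evaluation metrics."""

    subject_id: str
    r2: float
    mae: float
    mse: float
    meb: float
    aoc: float | None = None
    method: str | None = None
    wavelength_label: str | None = None


def _errors(measured_c, predicted_c) -> np.ndarray:
    m = np.asarray(measured_c, dtype=float)
    p = np.asarray(predicted_c, dtype=float)
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: measured {m.shape}, predicted {p.shape}")
    if m.size < 2:
        raise ValueError("need at least 2 samples")
    return p - m


def prediction_metrics(measured_c, predicted_c, subject_id: str = "",
                       r2_definition: str = "pearson",
                       **labels) -> MetricsReport:
    """Compute R^2, MAE, MSE, MEB for one prediction.

    ``r2_definition`` is ``'pearson'`` (squared correlation, offset-tolerant)
    or ``'explained'`` (1 - SS_res/SS_tot). Constant measured temperature
    makes R^2 undefined (NaN sentinel); the error metrics are still computed.
    """
    e = _errors(measured_c, predicted_c)
    m = np.asarray(measured_c, dtype=float)
    p = np.asarray(predicted_c, dtype=float)
    if np.ptp(m) == 0 or np.ptp(p) == 0:
        r2 = float("nan")
    elif r2_definition == "pearson":
        r2 = float(pearsonr(m, p).statistic ** 2)
    elif r2_definition == "explained":
        r2 = float(1.0 - np.sum(e**2) / np.sum((m - m.mean()) ** 2))
    else:
        raise ValueError(f"unknown r2_definition {r2_definition!r}")
    return MetricsReport(
        subject_id=subject_id,
        r2=r2,
        mae=float(np.mean(np.abs(e))),
        mse=float(np.mean(e**2)),
        meb=float(np.mean(e)),
        **labels,
    )


@dataclass(frozen=True)
class RROCCurve:
    """Shift-parameterised over/under-estimation curve (per-sample totals)."""

    shifts: np.ndarray
    over: np.ndarray
    under: np.ndarray
    aoc: float
    meb: float

    def __post_init__(self):
        for name in ("shifts", "over", "under"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shift": self.shifts, "over": self.over,
                             "under": self.under})


def _over_under(e: np.ndarray, shifts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    es = e[None, :] + shifts[:, None]
    over = np.maximum(es, 0.0).sum(axis=1) / e.size
    under = np.minimum(es, 0.0).sum(axis=1) / e.size
    return over, under


def rroc_curve(measured_c, predicted_c, n_shifts: int = 512) -> RROCCurve:
    """Construct the RROC curve of a prediction.

    The shift grid spans the full transition [-max(e), -min(e)] (outside it
    one of OVER/UNDER is identically zero, the curve's asymptote ends) and
    always includes the exact breakpoints -e_i, making OVER/UNDER piecewise
    linear between consecutive grid points; the AOC (trapezoidal area
    between the curve and the OVER axis) is therefore exact.
    """
    e = _errors(measured_c, predicted_c)
    s_lo, s_hi = -np.max(e), -np.min(e)
    if s_hi == s_lo:  # constant error: curve hugs the axes
        shifts = np.array([s_lo, s_hi])
    else:
        shifts = np.union1d(np.linspace(s_lo, s_hi, max(n_shifts, 2)), -e)
    over, under = _over_under(e, shifts)
    aoc = float(np.trapezoid(-under, over))
    return RROCCurve(shifts=shifts, over=over, under=under, aoc=aoc,
                     meb=float(np.mean(e)))


def dominance(curve_a: RROCCurve, curve_b: RROCCurve, tol: float = 1e-9) -> str:
    """Compare two RROC curves pointwise on a merged OVER grid.

    Returns ``'a_dominates'``, ``'b_dominates'`` or ``'crossing'``; curves
    that coincide within ``tol`` everywhere report ``'crossing'``.
    """
    for c in (curve_a, curve_b):
        if c.over.size == 0:
            raise ValueError("empty RROC curve")
    hi = min(curve_a.over[-1], curve_b.over[-1])
    grid = np.union1d(curve_a.over, curve_b.over)
    grid = grid[(grid >= 0) & (grid <= hi)]
    ua = np.interp(grid, curve_a.over, curve_a.under)
    ub = np.interp(grid, curve_b.over, curve_b.under)
    diff = ua - ub  # above = less negative UNDER
    a_above = bool(np.all(diff >= -tol) and np.any(diff > tol))
    b_above = bool(np.all(-diff >= -tol) and np.any(-diff > tol))
    if a_above and not b_above:
        return "a_dominates"
    if b_above and not a_above:
        return "b_dominates"
    return "crossing"


def metric_correlations(reports: Sequence[MetricsReport]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values over {MAE, MSE, AOC, MEB}.

    Returns ``(r, p)`` DataFrames, symmetric with unit diagonal; pairs
    involving a constant metric get a NaN sentinel.
    """
    if len(reports) < 3:
        raise ValueError("need at least 3 reports")
    cols = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(rep, name) for rep in reports], dtype=float)
        if np.any(np.isnan(vals)):
            raise ValueError(f"metric {name} missing (NaN) in some reports")
        cols[name] = vals
    n = len(METRIC_NAMES)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = cols[METRIC_NAMES[i]], cols[METRIC_NAMES[j]]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                res = pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
    labels = [m.upper() for m in METRIC_NAMES]
    return (pd.DataFrame(r, index=labels, columns=labels),
            pd.DataFrame(p, index=labels, columns=labels))
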