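"""Cross-validation error metrics for interpolated climate surfaces.

For each validation unit (a day, month or year) and variable, the suite
reports MAE and RMSE of predicted vs. true values, a truth-on-prediction
regression (true values regressed on predictions: slope, R², p), and —
across a declared comparison set of units — max–min normalized NMAE and
NRMSE, so the best unit in the set scores 0 and the worst 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "error_metrics",
    "minmax_normalize",
    "truth_on_prediction_fit",
    "validation_report",
]


def error_metrics(predicted, true):
    """(MAE, RMSE) of two aligned sequences."""
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.size != t.size:
        raise ValueError("predicted and true sequences must align")
    if p.size == 0:
        raise ValueError("need at least one pair")
    err = p - t
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err ** 2)))


def minmax_normalize(values) -> np.ndarray:
    """Max–min normalization: (v − min)/(max − min), in [0, 1].

    Affine-invariant (a·v + b with a > 0 gives identical output) and
    idempotent after one application.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ValueError("degenerate range: all values equal")
    return (v - lo) / (hi - lo)


def truth_on_prediction_fit(predicted, true):
    """OLS of true on predicted: (slope, R², two-sided p of the slope)."""
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.size != t.size or p.size < 3:
        raise ValueError("need at least 3 aligned pairs")
    if np.ptp(p) == 0:
        raise ValueError("degenerate fit: constant predictor")
    res = stats.linregress(p, t)
    return float(res.slope), float(res.rvalue ** 2), float(res.pvalue)


_GROUPERS = {
    "day": lambda d: d.strftime("%Y-%m-%d"),
    "month": lambda d: d.strftime("%Y-%m"),
    "year": lambda d: d.strftime("%Y"),
}


def validation_report(df: pd.DataFrame, group_by: str = "day",
                      date_col: str = "date", var_col: str = "variable",
                      pred_col: str = "predicted", true_col: str = "true"
                      ) -> pd.DataFrame:
    """Per-unit validation table with NMAE/NRMSE across each variable group.

    ``group_by`` sets the timescale of a unit (day, month or year).  The
    NMAE/NRMSE columns max–min normalize the MAE/RMSE columns within each
    variable's set of units, so they compare units of the same variable.
    """
    if group_by not in _GROUPERS:
        raise ValueError("group_by must be one of 'day', 'month', 'year'")
    dates = pd.to_datetime(df[date_col])
    unit = _GROUPERS[group_by](dates.dt)
    rows = []
    for (u, var), sub in df.assign(_unit=unit).groupby(["_unit", var_col]):
        mae, rmse = error_metrics(sub[pred_col], sub[true_col])
        slope, r2, p = truth_on_prediction_fit(sub[pred_col], sub[true_col])
        rows.append({"unit": u, "variable": var, "slope": slope, "r2": r2,
                     "p": p, "mae": mae, "rmse": rmse})
    out = pd.DataFrame(rows)
    for var, idx in out.groupby("variable").groups.items():
        if len(idx) >= 2 and out.loc[idx, "mae"].nunique() > 1:
            out.loc[idx, "nmae"] = minmax_normalize(out.loc[idx, "mae"])
        if len(idx) >= 2 and out.loc[idx, "rmse"].nunique() > 1:
            out.loc[idx, "nrmse"] = minmax_normalize(out.loc[idx, "rmse"])
    return out
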