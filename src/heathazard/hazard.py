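"""Composite heatwave hazard, trends, and relative-change diagnostics.

The annual hazard at a pixel is the equal-weight mean of the three annual
indicators — heatwave frequency (HWF), maximum event heat index (HWMHI) and
maximum event duration (HWMD) — each first normalized by its single maximum
over the full space-time domain, so hazard values are comparable from year
to year and lie in [0, 1].  AH (average hazard) is the multi-year mean per
pixel.

Trend diagnostics fit ordinary least squares of a value on the year, with a
two-sided t-test on the slope; the significance mask is ``p < alpha``.

Relative change of an indicator between the first and last five study years:

    RC = (mean over LY − mean over FY) / mean over the full period,

dimensionless and scale-invariant; RC > 0.8 is read as a sharp increase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "HazardScorer",
    "normalize_indicators",
    "hazard_score",
    "average_hazard",
    "linear_trend",
    "relative_change",
    "relative_change_table",
    "RC_SHARP_INCREASE",
]

INDICATORS = ("hwf", "hwmhi", "hwmd")
#: RC above this level is classified as a sharp increase.
RC_SHARP_INCREASE = 0.8


class HazardScorer(BaseEstimator):
    """Normalize annual indicators and combine them into the hazard score.

    Parameters
    ----------
    scope : {"global", "pixel"}
        "global" (default) normalizes each indicator by its one maximum over
        all pixels and years, keeping hazard comparable across space and
        time; "pixel" uses per-pixel maxima instead.

    Attributes
    ----------
    maxima_ : dict
        The normalization maximum per indicator (arrays for scope="pixel").
    """

    def __init__(self, scope: str = "global"):
        self.scope = scope

    def fit(self, indicators: dict):
        """Record normalization maxima from ``{"hwf": ..., ...}`` stacks.

        Each stack is shaped (n_years, *space); all three must align.
        """
        if self.scope not in ("global", "pixel"):
            raise ValueError("scope must be 'global' or 'pixel'")
        shapes = {np.asarray(indicators[k]).shape for k in INDICATORS}
        if len(shapes) != 1:
            raise ValueError("indicator stacks must share a shape")
        self.maxima_ = {}
        for k in INDICATORS:
            arr = np.asarray(indicators[k], dtype=float)
            if np.nanmin(arr) < 0:
                raise ValueError(f"indicator {k} has negative values")
            mx = (np.nanmax(arr) if self.scope == "global"
                  else np.nanmax(arr, axis=0))
            self.maxima_[k] = mx
        return self

    def transform(self, indicators: dict) -> np.ndarray:
        """Hazard stack in [0, 1]: mean of the three normalized indicators."""
        normed = [self._normalize_one(k, indicators[k]) for k in INDICATORS]
        return np.mean(normed, axis=0)

    def fit_transform(self, indicators: dict) -> np.ndarray:
        return self.fit(indicators).transform(indicators)

    def _normalize_one(self, key: str, arr) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if np.nanmin(arr) < 0:
            raise ValueError(f"indicator {key} has negative values")
        mx = self.maxima_[key]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(mx > 0, arr / mx, 0.0)  # all-zero indicator -> 0
        return out


def normalize_indicators(indicators: dict, scope: str = "global") -> dict:
    """Each indicator divided by its domain maximum; results in [0, 1]."""
    scorer = HazardScorer(scope=scope).fit(indicators)
    return {k: scorer._normalize_one(k, indicators[k]) for k in INDICATORS}


def hazard_score(norm_hwf, norm_hwmhi, norm_hwmd) -> np.ndarray:
    """Equal-weight mean of three already-normalized indicator stacks."""
    arrs = [np.asarray(a, dtype=float) for a in (norm_hwf, norm_hwmhi, norm_hwmd)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("normalized stacks must share a shape")
    return np.mean(arrs, axis=0)


def average_hazard(hazard) -> np.ndarray:
    """Per-pixel mean hazard over the year axis (axis 0)."""
    return np.asarray(hazard, dtype=float).mean(axis=0)


def linear_trend(values, years, alpha: float = 0.05):
    """Per-pixel OLS trend of ``values`` (year axis first) on ``years``.

    Returns a dict with ``slope`` (units per year), two-sided ``p`` from the
    t-distribution, ``r2``, and the ``significant`` mask (p < alpha).
    Requires at least 3 years and a non-constant year axis; series that are
    exactly constant get slope 0, R² 0 and p = 1.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(years, dtype=float)
    n = t.size
    if y.shape[0] != n:
        raise ValueError("year axis of values must match years")
    if n < 3:
        raise ValueError("need at least 3 years for a trend")
    if np.ptp(t) == 0:
        raise ValueError("time axis is constant")
    tc = t - t.mean()
    sxx = float(np.sum(tc ** 2))
    shape_sp = y.shape[1:]
    yf = y.reshape(n, -1)
    flat = np.ptp(yf, axis=0) == 0
    slope = (tc @ yf) / sxx
    slope[flat] = 0.0
    resid = yf - yf.mean(axis=0) - np.outer(tc, slope)
    sse = np.sum(resid ** 2, axis=0)
    sst = np.sum((yf - yf.mean(axis=0)) ** 2, axis=0)
    dof = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / dof / sxx)
        tstat = np.where(se > 0, slope / se, 0.0)
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    # zero residual error: p = 0 for an exact non-flat line, 1 for a constant
    p = np.where(se > 0, p, np.where(slope != 0, 0.0, 1.0))
    p = np.where(flat, 1.0, p)
    r2 = np.where(flat, 0.0, r2)
    out = {"slope": slope.reshape(shape_sp), "p": p.reshape(shape_sp),
           "r2": r2.reshape(shape_sp)}
    out["significant"] = out["p"] < alpha
    if shape_sp == ():
        out = {k: (v.item() if k != "significant" else bool(v))
               for k, v in out.items()}
    return out


def relative_change(series, years=None, fy=None, ly=None, window: int = 5):
    """Relative change between the first and last ``window`` study years.

    ``RC = (mean(LY) − mean(FY)) / mean(full period)``.  ``fy``/``ly`` may
    name explicit year lists; by default they are the first/last ``window``
    years of ``years`` (or of the series index positions).  Returns NaN when
    the full-period mean is zero (RC undefined).
    """
    v = np.asarray(series, dtype=float)
    if years is None:
        years = np.arange(v.shape[0])
    years = np.asarray(years)
    if v.shape[0] != years.size:
        raise ValueError("series and years must align")
    order = np.argsort(years, kind="stable")
    yrs, v = years[order], v[order]
    fy = yrs[:window] if fy is None else np.asarray(fy)
    ly = yrs[-window:] if ly is None else np.asarray(ly)
    if np.intersect1d(fy, ly).size:
        raise ValueError("FY and LY windows must be disjoint")
    m_fy = v[np.isin(yrs, fy)].mean(axis=0)
    m_ly = v[np.isin(yrs, ly)].mean(axis=0)
    m_all = v.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = np.where(m_all != 0, (m_ly - m_fy) / m_all, np.nan)
    return float(rc) if rc.ndim == 0 else rc


def relative_change_table(df: pd.DataFrame, value_col: str, year_col: str = "year",
                          group_cols=("indicator",), window: int = 5) -> pd.DataFrame:
    """Group-wise RC: average the value within each (group, year) first,
    then apply the RC formula to the resulting annual series.

    ``group_cols`` typically name the indicator plus a region and/or month
    column.  Adds a ``sharp_increase`` flag (RC > 0.8).
    """
    group_cols = list(group_cols)
    annual = (df.groupby(group_cols + [year_col])[value_col]
                .mean().reset_index())
    rows = []
    for key, sub in annual.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        rc = relative_change(sub[value_col].to_numpy(),
                             sub[year_col].to_numpy(), window=window)
        rows.append(dict(zip(group_cols, key)) | {
            "rc": rc, "sharp_increase": bool(rc > RC_SHARP_INCREASE)})
    return pd.DataFrame(rows)
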