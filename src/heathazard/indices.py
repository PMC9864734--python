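"""Torridity index, local torridity thresholds, and the daily heat index.

The torridity index (TI) is an apparent-heat metric combining daily maximum
temperature MT (°C) and mean relative humidity RH (%):

    TI = 1.8·MT + 32 − 0.55·(1.8·MT − 26)·f(RH)

with the humidity factor ``f = 1 − 0.6`` for RH ≤ 60 % and ``f = 1 − RH/100``
for RH > 60 % (the two branches agree at 60 %).  TI lands on a
Fahrenheit-like, dimensionless scale.

A location's torridity threshold TI′ is the 50th quantile — computed with a
specific plotting-position rule, see :func:`quantile_paper` — of TI over all
days whose MT exceeds a hot-sample cutoff (33 °C by default), pooled across
every year of the record.  Days with TI ≥ TI′ are *hot days*.

The daily heat index (HI) grades each hot day, rewarding persistence: with
Δ = TI − TI′ for the current day, Δ_i the exceedance of the i-th immediately
preceding consecutive hot day, and N such preceding days,

    HI = 1.2·Δ + 0.35·Σ_{i=1..N} Δ_i / i + 0.15·Σ_{i=1..N−1} 1/(i+1).

The third term depends only on the run length (a pure persistence bonus).
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr
from sklearn.base import BaseEstimator

__all__ = [
    "torridity_index",
    "invert_torridity",
    "quantile_paper",
    "TorridityThreshold",
    "ti_threshold",
    "heat_index_day",
    "heat_index_field",
]

#: Default hot-sample cutoff on daily maximum temperature, °C.
HOT_SAMPLE_CUTOFF = 33.0
#: Default quantile level for the local threshold.
THRESHOLD_QUANTILE = 0.50
#: Minimum pooled hot samples for a pixel's TI′ to be considered stable.
MIN_SAMPLES = 10


def _humidity_factor(rh):
    rh = np.asarray(rh, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (rh < 0.0) | (rh > 100.0)
    if np.any(bad & np.isfinite(rh)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    return np.where(rh <= 60.0, 0.4, 1.0 - rh / 100.0)


def torridity_index(mt, rh):
    """Torridity index from daily maximum temperature (°C) and RH (%).

    Elementwise over arrays of any matching shape; NaNs propagate.
    """
    mt = np.asarray(mt, dtype=float)
    f = _humidity_factor(rh)
    return 1.8 * mt + 32.0 - 0.55 * (1.8 * mt - 26.0) * f


def invert_torridity(ti, rh):
    """Daily maximum temperature (°C) that yields ``ti`` at humidity ``rh``.

    Exact inverse of :func:`torridity_index` in MT for fixed RH (the formula
    is affine in MT once the humidity branch is fixed).
    """
    ti = np.asarray(ti, dtype=float)
    f = _humidity_factor(rh)
    return (ti - 32.0 - 0.55 * 26.0 * f) / (1.8 * (1.0 - 0.55 * f))


def quantile_paper(x, p: float) -> float:
    """Quantile of ``x`` with the plotting-position rule used for TI′.

    The sample is sorted ascending; with n values and level ``p`` the
    (1-based) interpolation index is ``p·n + (1 + p)/3``, split into integer
    part ``j`` and fraction ``γ``, and the quantile is
    ``(1 − γ)·X(j) + γ·X(j+1)``.

    Boundary rule: when ``j ≥ n`` the top order statistic X(n) is returned
    (γ forced to 0); symmetrically, when ``j < 1`` the bottom order statistic
    X(1) is returned.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("quantile of an empty sample is undefined")
    if not 0.0 < p < 1.0:
        raise ValueError("quantile level p must lie in (0, 1)")
    idx = p * n + (1.0 + p) / 3.0
    j = int(idx)
    gamma = idx - j
    if j >= n:
        return float(x[n - 1])
    if j < 1:
        return float(x[0])
    return float((1.0 - gamma) * x[j - 1] + gamma * x[j])


class TorridityThreshold(BaseEstimator):
    """Estimate the local torridity threshold TI′ per pixel.

    Pools, per pixel, every day across all years with MT above
    ``hot_sample_cutoff``, computes the torridity index of those samples and
    takes the level-``p`` quantile (:func:`quantile_paper`).  Pixels with
    fewer than ``min_samples`` hot samples are flagged invalid (their TI′ is
    NaN, never zero-filled).

    Parameters
    ----------
    hot_sample_cutoff : float
        MT cutoff (°C) selecting the hot-sample pool.  Default 33.
    p : float
        Quantile level in (0, 1).  Default 0.50.
    min_samples : int
        Minimum pool size for a valid threshold.  Default 10.

    Attributes
    ----------
    threshold_ : ndarray
        TI′ per pixel (NaN where invalid).  Scalar inputs give a 0-d array.
    n_samples_ : ndarray of int
        Hot-sample pool size per pixel.
    valid_ : ndarray of bool
        True where ``n_samples_ >= min_samples``.
    """

    def __init__(self, hot_sample_cutoff: float = HOT_SAMPLE_CUTOFF,
                 p: float = THRESHOLD_QUANTILE, min_samples: int = MIN_SAMPLES):
        self.hot_sample_cutoff = hot_sample_cutoff
        self.p = p
        self.min_samples = min_samples

    def fit(self, mt, rh=None):
        """Fit on daily stacks shaped (time, ...); ``mt`` may be a Dataset.

        Accepts either two arrays (MT, RH) with the time axis first, or an
        :class:`xarray.Dataset` holding ``mt``/``rh`` variables.
        """
        if isinstance(mt, xr.Dataset):
            rh = mt["rh"].values
            mt = mt["mt"].values
        mt = np.asarray(mt, dtype=float)
        rh = np.asarray(rh, dtype=float)
        if mt.shape != rh.shape:
            raise ValueError("MT and RH stacks must share a shape")
        ntime = mt.shape[0]
        space = mt.shape[1:]
        mt2 = mt.reshape(ntime, -1)
        rh2 = rh.reshape(ntime, -1)
        npix = mt2.shape[1]
        thr = np.full(npix, np.nan)
        cnt = np.zeros(npix, dtype=int)
        for k in range(npix):
            sel = mt2[:, k] > self.hot_sample_cutoff
            sel &= np.isfinite(mt2[:, k]) & np.isfinite(rh2[:, k])
            m = int(sel.sum())
            cnt[k] = m
            if m >= self.min_samples:
                ti = torridity_index(mt2[sel, k], rh2[sel, k])
                thr[k] = quantile_paper(ti, self.p)
        self.threshold_ = thr.reshape(space)
        self.n_samples_ = cnt.reshape(space)
        self.valid_ = self.n_samples_ >= self.min_samples
        if not self.valid_.any():
            warnings.warn("no pixel has enough hot samples for a threshold",
                          stacklevel=2)
        return self

    def transform(self, mt, rh=None):
        """Hot-day mask (TI ≥ TI′) for daily stacks aligned with the fit grid."""
        if isinstance(mt, xr.Dataset):
            rh = mt["rh"].values
            mt = mt["mt"].values
        ti = torridity_index(mt, rh)
        mask = ti >= self.threshold_
        return np.where(np.isfinite(self.threshold_), mask, False)


def ti_threshold(mt, rh, hot_sample_cutoff: float = HOT_SAMPLE_CUTOFF,
                 p: float = THRESHOLD_QUANTILE, min_samples: int = MIN_SAMPLES):
    """Per-pixel TI′ and validity from daily MT/RH stacks (time first).

    Thin wrapper over :class:`TorridityThreshold`; returns
    ``(threshold, n_samples, valid)``.
    """
    est = TorridityThreshold(hot_sample_cutoff=hot_sample_cutoff, p=p,
                             min_samples=min_samples).fit(mt, rh)
    return est.threshold_, est.n_samples_, est.valid_


def heat_index_day(ti_prefix, ti_prime: float) -> float:
    """Heat index of the last day of ``ti_prefix``.

    ``ti_prefix`` holds the TIs of the N immediately preceding consecutive
    hot days followed by the current day's TI (so its length is N + 1).  The
    current day must itself be hot (TI ≥ TI′).
    """
    ti = np.asarray(ti_prefix, dtype=float).ravel()
    if ti.size == 0:
        raise ValueError("prefix must contain at least the current day")
    delta = ti - float(ti_prime)
    if delta[-1] < 0:
        raise ValueError("heat index is defined only on hot days (TI >= TI')")
    n_prev = ti.size - 1
    hi = 1.2 * delta[-1]
    if n_prev:
        i = np.arange(1, n_prev + 1, dtype=float)
        hi += 0.35 * float(np.sum(delta[-2::-1][: n_prev] / i))
        hi += 0.15 * float(np.sum(1.0 / (i[: n_prev - 1] + 1.0)))
    return float(hi)


def _run_heat_index(delta_run: np.ndarray) -> np.ndarray:
    # HI for every day of one hot run, given the run's exceedances Δ.
    L = delta_run.size
    out = np.empty(L)
    inv = 1.0 / np.arange(1, L + 1, dtype=float)
    # persistence bonus: 0.15·(H_q − 1) for q ≥ 1 preceding days
    harm = np.concatenate(([0.0], np.cumsum(inv)))
    for q in range(L):
        lag = np.sum(delta_run[q - 1 :: -1][:q] * inv[:q]) if q else 0.0
        bonus = 0.15 * (harm[q] - 1.0) if q >= 1 else 0.0
        out[q] = 1.2 * delta_run[q] + 0.35 * lag + bonus
    return out


def heat_index_field(ti, threshold, season_id=None):
    """Daily heat index over a stack, masked (NaN) outside hot days.

    Parameters
    ----------
    ti : ndarray, shape (time, ...)
        Daily torridity index.
    threshold : ndarray broadcastable to ``ti.shape[1:]``
        Per-pixel TI′ (NaN marks invalid pixels, which stay fully masked).
    season_id : ndarray of int, shape (time,), optional
        Season label per layer; lag terms never cross a change of label
        (use one label per May–September window).  Default: one season.

    Returns
    -------
    hi : ndarray like ``ti``; NaN on non-hot days and invalid pixels.
    lag : ndarray of int; number of preceding consecutive hot days used
        (−1 outside hot days).
    """
    ti = np.asarray(ti, dtype=float)
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), ti.shape[1:])
    ntime = ti.shape[0]
    if season_id is None:
        season_id = np.zeros(ntime, dtype=int)
    season_id = np.asarray(season_id)
    if season_id.shape != (ntime,):
        raise ValueError("season_id must have one entry per time layer")

    ti2 = ti.reshape(ntime, -1)
    thr2 = thr.ravel()
    hi = np.full_like(ti2, np.nan)
    lag = np.full(ti2.shape, -1, dtype=int)
    bounds = _season_bounds(season_id)
    for k in range(ti2.shape[1]):
        t0 = thr2[k]
        if not np.isfinite(t0):
            continue
        col = ti2[:, k]
        hot = col >= t0
        for a, b in bounds:
            for s, ln in find_runs_bool(hot[a:b]):
                sl = slice(a + s, a + s + ln)
                hi[sl, k] = _run_heat_index(col[sl] - t0)
                lag[sl, k] = np.arange(ln)
    return hi.reshape(ti.shape), lag.reshape(ti.shape)


def _season_bounds(season_id: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of each contiguous season block."""
    if season_id.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(season_id) != 0) + 1
    edges = np.concatenate(([0], cuts, [season_id.size]))
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def find_runs_bool(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length) pairs, in order."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate(([False], m, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, stops)]
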