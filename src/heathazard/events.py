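"""Heatwave event detection and annual hazard indicators.

A heatwave is a run of at least ``min_duration`` (default 3) consecutive hot
days (TI ≥ TI′) whose event-level heatwave index HWI passes a threshold
(default 2.8).  HWI summarizes the run's daily heat indices; the default is
their mean — the 2.8 cutoff is a daily-grade criterion, coherent with the
mean — while the plain sum over the run is available as ``hwi_mode="sum"``
(the two differ exactly by the factor N, the run duration).

Runs are evaluated within one May–September window; no event bridges the
September → May gap, and an event belongs to the calendar year it starts in.

Annual indicators per pixel and year:

* HWF   — number of heatwave events,
* HWMHI — maximum daily HI over the year's events,
* HWMD  — longest event duration (days).

All three are 0 for a pixel-year without events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .indices import find_runs_bool, _season_bounds

__all__ = [
    "HeatwaveEvent",
    "hot_day_mask",
    "find_runs",
    "HeatwaveDetector",
    "detect_events",
    "detect_events_grid",
    "annual_indicators",
]


@dataclass(frozen=True)
class HeatwaveEvent:
    """One detected heatwave at a pixel or station."""

    pixel: tuple  # (iy, ix) for grids, (station_id,) for series
    year: int
    start: int  # day-of-season index (0-based) of the first event day
    duration: int  # N, days
    hwi: float
    max_hi: float
    ti: tuple = field(default=(), repr=False)
    hi: tuple = field(default=(), repr=False)

    @property
    def end(self) -> int:
        """Day-of-season index of the last event day (inclusive)."""
        return self.start + self.duration - 1


def hot_day_mask(ti, threshold):
    """Binary hot-day stack: 1 where TI ≥ TI′, 0 otherwise.

    Pixels with an invalid (NaN) threshold are fully masked (NaN in the
    returned float array).
    """
    ti = np.asarray(ti, dtype=float)
    thr = np.asarray(threshold, dtype=float)
    if thr.shape != ti.shape[1:] and thr.shape != ():
        raise ValueError("threshold shape must match the spatial grid")
    mask = (ti >= thr).astype(float)
    invalid = ~np.isfinite(thr)
    if invalid.ndim:
        mask[:, invalid] = np.nan
    elif invalid:
        mask[:] = np.nan
    return mask


def find_runs(mask) -> list[tuple[int, int]]:
    """Maximal runs of 1s in a binary sequence, as (start, length) pairs."""
    m = np.asarray(mask)
    vals = m[np.isfinite(m)] if m.dtype.kind == "f" else m
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("find_runs expects a binary (0/1) sequence")
    return find_runs_bool(np.nan_to_num(m.astype(float)) == 1)


class HeatwaveDetector(BaseEstimator):
    """Detect heatwave events from daily TI and HI series.

    Parameters
    ----------
    min_duration : int
        Minimum run length in days (default 3).
    hwi_threshold : float
        Minimum HWI for a run to count as a heatwave (default 2.8).
    hwi_mode : {"mean", "sum"}
        Event HWI as the mean of daily HI (default) or their sum.
    """

    def __init__(self, min_duration: int = 3, hwi_threshold: float = 2.8,
                 hwi_mode: str = "mean"):
        self.min_duration = min_duration
        self.hwi_threshold = hwi_threshold
        self.hwi_mode = hwi_mode

    def _check(self):
        if self.hwi_mode not in ("mean", "sum"):
            raise ValueError("hwi_mode must be 'mean' or 'sum'")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")

    def detect(self, ti, hi, ti_prime, *, years=None, pixel=()) -> list[HeatwaveEvent]:
        """Events in one location's daily series.

        ``years`` labels each day with its season's calendar year (runs never
        cross a change of label); by default the whole series is one season
        of year 0.
        """
        self._check()
        ti = np.asarray(ti, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if ti.shape != hi.shape:
            raise ValueError("TI and HI series must be aligned")
        if not np.isfinite(ti_prime):
            return []
        if years is None:
            years = np.zeros(ti.size, dtype=int)
        years = np.asarray(years)
        hot = ti >= float(ti_prime)
        events: list[HeatwaveEvent] = []
        for a, b in _season_bounds(years):
            for s, ln in find_runs_bool(hot[a:b]):
                if ln < self.min_duration:
                    continue
                sl = slice(a + s, a + s + ln)
                daily = hi[sl]
                hwi = float(daily.sum() if self.hwi_mode == "sum"
                            else daily.mean())
                if hwi < self.hwi_threshold:
                    continue
                events.append(HeatwaveEvent(
                    pixel=tuple(pixel), year=int(years[a]), start=s,
                    duration=ln, hwi=hwi, max_hi=float(daily.max()),
                    ti=tuple(ti[sl]), hi=tuple(daily)))
        return events

    def detect_grid(self, ti, hi, threshold, years) -> list[HeatwaveEvent]:
        """Events over a (time, ny, nx) stack; ``years`` labels each layer."""
        self._check()
        ti = np.asarray(ti, dtype=float)
        hi = np.asarray(hi, dtype=float)
        thr = np.asarray(threshold, dtype=float)
        events: list[HeatwaveEvent] = []
        for iy in range(ti.shape[1]):
            for ix in range(ti.shape[2]):
                if not np.isfinite(thr[iy, ix]):
                    continue
                events.extend(self.detect(ti[:, iy, ix], hi[:, iy, ix],
                                          thr[iy, ix], years=years,
                                          pixel=(iy, ix)))
        return events


def detect_events(ti, hi, ti_prime, min_duration: int = 3,
                  hwi_threshold: float = 2.8, hwi_mode: str = "mean",
                  years=None, pixel=()) -> list[HeatwaveEvent]:
    """Functional wrapper over :meth:`HeatwaveDetector.detect`."""
    det = HeatwaveDetector(min_duration=min_duration,
                           hwi_threshold=hwi_threshold, hwi_mode=hwi_mode)
    return det.detect(ti, hi, ti_prime, years=years, pixel=pixel)


def detect_events_grid(ti, hi, threshold, years, **kwargs) -> list[HeatwaveEvent]:
    """Functional wrapper over :meth:`HeatwaveDetector.detect_grid`."""
    return HeatwaveDetector(**kwargs).detect_grid(ti, hi, threshold, years)


def annual_indicators(events, years, shape=None):
    """Aggregate events into per-pixel, per-year HWF / HWMHI / HWMD.

    Parameters
    ----------
    events : iterable of HeatwaveEvent
    years : sequence of int
        Every year of the study period (pixel-years without events get 0s).
    shape : (ny, nx), optional
        Spatial grid shape; inferred as the max pixel index + 1 if omitted.
        Pass ``()`` (or use 1-tuple pixels) for station series.

    Returns
    -------
    dict with arrays ``hwf`` (int), ``hwmhi``, ``hwmd`` shaped
    (n_years, *shape), plus the ``years`` axis.  Station-keyed events
    (non-integer pixels) are aggregated into a DataFrame instead via
    :func:`events_table`.
    """
    events = list(events)
    years = np.asarray(sorted(set(int(y) for y in years)))
    if shape is None:
        if events:
            shape = tuple(int(max(e.pixel[d] for e in events)) + 1
                          for d in range(len(events[0].pixel)))
        else:
            shape = ()
    yidx = {int(y): i for i, y in enumerate(years)}
    hwf = np.zeros((years.size, *shape), dtype=int)
    hwmhi = np.zeros((years.size, *shape))
    hwmd = np.zeros((years.size, *shape), dtype=int)
    for e in events:
        if e.year not in yidx:
            raise ValueError(f"event year {e.year} outside the year axis")
        key = (yidx[e.year], *map(int, e.pixel))
        hwf[key] += 1
        hwmhi[key] = max(hwmhi[key], e.max_hi)
        hwmd[key] = max(hwmd[key], e.duration)
    return {"years": years, "hwf": hwf, "hwmhi": hwmhi, "hwmd": hwmd}


def events_table(events) -> pd.DataFrame:
    """Events as a tidy table (one row per event)."""
    rows = [{
        "pixel": "/".join(map(str, e.pixel)), "year": e.year,
        "start": e.start, "end": e.end, "duration": e.duration,
        "hwi": e.hwi, "max_hi": e.max_hi,
    } for e in events]
    cols = ["pixel", "year", "start", "end", "duration", "hwi", "max_hi"]
    return pd.DataFrame(rows, columns=cols)
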