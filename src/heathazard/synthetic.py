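"""Synthetic daily climate with injected, recoverable heatwave episodes.

Generates extended-summer (May 1 – September 30, always 153 days) stacks of
daily maximum temperature MT and mean relative humidity RH, either as a
gridded field or as per-station series, with a ground-truth catalog of
injected heat episodes so every downstream stage can be tested against
known answers.

The background model, per pixel and season:

* a smooth seasonal half-sine cycle, ``base + amp·sin(π(d + ½)/153)``,
  peaking in mid-July;
* day-to-day anomalies from a stationary first-order autoregressive process
  (heat builds over consecutive days, which the heat index's lag terms
  reward): ``a_t = ρ a_{t−1} + ε_t`` with innovations scaled so the marginal
  standard deviation equals ``anomaly_sd``;
* humidity as a clipped Gaussian linearly coupled to the temperature anomaly
  (negative coupling = dry heat, positive = humid heat), clipped to
  [0, 100] %.

Episodes ADD a temperature plateau on their target days rather than
overwriting, so the background field is bit-identical with and without
injection for the same seed.  Two extra construction steps make the truth
catalog exactly recoverable by the detector:

* **guard days** — one day on each flank of an episode is cooled, so the
  injected run is the maximal hot run (a warm background day can never
  extend it);
* **margin enforcement** — after injection the pixel's eventual torridity
  threshold TI′ is recomputed and any episode day whose TI falls short of
  TI′ + ``exceedance`` is lifted to it via the exact inverse of the
  torridity formula (a short fixed-point loop, since lifting can nudge TI′).

Pixels are spatially independent (an optional Gaussian smoothing kernel on
the anomaly field is the only spatial structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import indices
from .indices import invert_torridity, ti_threshold, torridity_index

__all__ = [
    "SEASON_DAYS",
    "EpisodeTruth",
    "StationSpec",
    "SyntheticConfig",
    "generate_grid",
    "generate_station_series",
    "truth_catalog",
    "season_dates",
    "load_config",
    "save_config",
]

#: Days in the May 1 – September 30 window (leap years do not change it).
SEASON_DAYS = 153


@dataclass(frozen=True)
class EpisodeTruth:
    """Ground truth for one injected heat episode.

    ``target`` is a grid pixel ``(iy, ix)`` or a station id string.
    ``start`` is the 0-based day-of-season index; the episode covers days
    ``start .. start + duration − 1`` of the given year's window.
    ``exceedance`` is the TI margin (index units) every episode day is
    guaranteed to hold above the pixel's eventual TI′.
    """

    target: tuple | str
    year: int
    start: int
    duration: int
    exceedance: float = 2.0
    mt_boost: float | None = None  # None -> config.episode_boost
    rh_boost: float = 0.0

    @property
    def stop(self) -> int:
        """Exclusive day-of-season end index."""
        return self.start + self.duration


@dataclass(frozen=True)
class StationSpec:
    station_id: str
    lon: float
    lat: float
    elevation: float = 0.0


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic climate.

    Defaults describe a warm-temperate extended summer: the seasonal cycle
    peaks near 30 °C, so a realistic minority of days clear the 33 °C
    hot-sample cutoff and every pixel acquires a stable local threshold,
    while natural background heatwaves remain possible.
    """

    seed: int = 0
    shape: tuple[int, int] = (4, 4)  # (ny, nx)
    cell_size: float = 0.01  # degrees
    origin: tuple[float, float] = (110.0, 30.0)  # (lon, lat) of pixel (0, 0)
    years: tuple[int, int] = (1990, 2019)  # inclusive
    baseline_temp: float = 22.0  # °C
    seasonal_amplitude: float = 8.0  # °C
    anomaly_rho: float = 0.6  # AR(1) coefficient, [0, 1)
    anomaly_sd: float = 2.5  # °C, marginal
    humidity_mean: float = 65.0  # %
    humidity_sd: float = 10.0  # %
    humidity_coupling: float = -1.5  # % RH per °C of temperature anomaly
    episodes: list[EpisodeTruth] = field(default_factory=list)
    stations: list[StationSpec] = field(default_factory=list)
    episode_boost: float = 12.0  # °C plateau added on episode days
    guard_days: bool = True
    guard_drop: float = 10.0  # °C removed on flanking guard days
    smoothing_sigma: float = 0.0  # pixels; 0 disables
    enforce_margin: bool = True
    threshold_min_samples: int = indices.MIN_SAMPLES

    def validate(self) -> None:
        ny, nx = self.shape
        if ny < 1 or nx < 1:
            raise ValueError("grid shape must be positive")
        if self.years[0] > self.years[1]:
            raise ValueError("year range is empty")
        if self.anomaly_sd <= 0:
            raise ValueError("anomaly standard deviation must be > 0")
        if not 0.0 <= self.anomaly_rho < 1.0:
            raise ValueError("anomaly autocorrelation must lie in [0, 1)")
        ids = {s.station_id for s in self.stations}
        for ep in self.episodes:
            if ep.duration < 1:
                raise ValueError("episode duration must be >= 1")
            if ep.start < 0 or ep.stop > SEASON_DAYS:
                raise ValueError("episode must lie within May-September")
            if not self.years[0] <= ep.year <= self.years[1]:
                raise ValueError("episode year outside the study period")
            if isinstance(ep.target, str):
                if ep.target not in ids:
                    raise KeyError(f"unknown station {ep.target!r}")
            else:
                iy, ix = ep.target
                if not (0 <= iy < ny and 0 <= ix < nx):
                    raise ValueError(f"episode pixel {ep.target} off-grid")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def season_dates(year: int) -> pd.DatetimeIndex:
    """The 153 daily dates of one extended summer."""
    return pd.date_range(f"{year}-05-01", f"{year}-09-30", freq="D")


def _seasonal_cycle(cfg: SyntheticConfig) -> np.ndarray:
    d = np.arange(SEASON_DAYS)
    return cfg.baseline_temp + cfg.seasonal_amplitude * np.sin(
        np.pi * (d + 0.5) / SEASON_DAYS)


def _background(cfg: SyntheticConfig, rng, space: tuple[int, ...]):
    """Background MT/RH shaped (n_years*153, *space)."""
    ny_t = cfg.n_years
    eps = rng.standard_normal((ny_t, SEASON_DAYS, *space))
    eta = rng.standard_normal((ny_t, SEASON_DAYS, *space))
    if cfg.smoothing_sigma > 0 and len(space) == 2:
        from scipy.ndimage import gaussian_filter
        sig = (0, 0, cfg.smoothing_sigma, cfg.smoothing_sigma)
        for arr in (eps, eta):
            sm = gaussian_filter(arr, sigma=sig, mode="wrap")
            sd = sm.std()
            arr[:] = sm / sd if sd > 0 else sm
    rho, sd = cfg.anomaly_rho, cfg.anomaly_sd
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    a = np.empty_like(eps)
    a[:, 0] = sd * eps[:, 0]  # stationary start, fresh each season
    for t in range(1, SEASON_DAYS):
        a[:, t] = rho * a[:, t - 1] + innov_sd * eps[:, t]
    mt = _seasonal_cycle(cfg).reshape(1, -1, *([1] * len(space))) + a
    rh = np.clip(cfg.humidity_mean + cfg.humidity_sd * eta
                 + cfg.humidity_coupling * a, 0.0, 100.0)
    flat = (ny_t * SEASON_DAYS, *space)
    return mt.reshape(flat), rh.reshape(flat)


def _episode_days(cfg: SyntheticConfig, ep: EpisodeTruth) -> np.ndarray:
    y0 = (ep.year - cfg.years[0]) * SEASON_DAYS
    return np.arange(y0 + ep.start, y0 + ep.stop)


def _inject(cfg: SyntheticConfig, mt, rh, episodes):
    """Apply plateaus, guard days and margin enforcement in place.

    ``mt``/``rh`` are (time,) series for one location; ``episodes`` the
    episodes targeting it.
    """
    covered = np.zeros(mt.shape[0], dtype=bool)
    for ep in episodes:
        covered[_episode_days(cfg, ep)] = True
    for ep in episodes:
        days = _episode_days(cfg, ep)
        boost = cfg.episode_boost if ep.mt_boost is None else ep.mt_boost
        mt[days] += boost
        if ep.rh_boost:
            rh[days] = np.clip(rh[days] + ep.rh_boost, 0.0, 100.0)
        if cfg.guard_days:
            y0 = (ep.year - cfg.years[0]) * SEASON_DAYS
            for g in (days[0] - 1, days[-1] + 1):
                if y0 <= g < y0 + SEASON_DAYS and not covered[g]:
                    mt[g] -= cfg.guard_drop
    if cfg.enforce_margin and episodes:
        _enforce_margin(cfg, mt, rh, episodes)


def _enforce_margin(cfg: SyntheticConfig, mt, rh, episodes, max_iter: int = 6):
    """Lift episode days until TI ≥ TI′ + exceedance holds at the pixel."""
    import warnings
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            thr, _, valid = ti_threshold(mt[:, None], rh[:, None],
                                         min_samples=cfg.threshold_min_samples)
        thr = float(thr[0])
        if not valid[0]:
            return  # threshold undefined here; margin is vacuous
        changed = False
        for ep in episodes:
            days = _episode_days(cfg, ep)
            target = thr + ep.exceedance
            ti = torridity_index(mt[days], rh[days])
            short = ti < target
            if short.any():
                mt[days[short]] = invert_torridity(target + 1e-9,
                                                   rh[days[short]])
                changed = True
        if not changed:
            return


def generate_grid(cfg: SyntheticConfig) -> xr.Dataset:
    """Gridded daily MT/RH for every extended summer of the study period.

    Returns an :class:`xarray.Dataset` with dims ``(time, lat, lon)``,
    variables ``mt`` (°C) and ``rh`` (%), and auxiliary coords ``year`` and
    ``doy`` (0-based day of season).  Deterministic in ``cfg.seed``.
    """
    cfg.validate()
    ny, nx = cfg.shape
    rng = np.random.default_rng(cfg.seed)
    mt, rh = _background(cfg, rng, (ny, nx))

    grid_eps: dict[tuple[int, int], list[EpisodeTruth]] = {}
    for ep in cfg.episodes:
        if not isinstance(ep.target, str):
            grid_eps.setdefault(tuple(ep.target), []).append(ep)
    for (iy, ix), eps in grid_eps.items():
        _inject(cfg, mt[:, iy, ix], rh[:, iy, ix], eps)

    time = pd.DatetimeIndex(np.concatenate(
        [season_dates(y).values for y in cfg.year_list]))
    year = np.repeat(cfg.year_list, SEASON_DAYS)
    doy = np.tile(np.arange(SEASON_DAYS), cfg.n_years)
    lon0, lat0 = cfg.origin
    ds = xr.Dataset(
        {"mt": (("time", "lat", "lon"), mt,
                {"units": "degC", "long_name": "daily maximum temperature"}),
         "rh": (("time", "lat", "lon"), rh,
                {"units": "percent", "long_name": "daily mean relative humidity"})},
        coords={"time": time,
                "lat": lat0 + cfg.cell_size * np.arange(ny),
                "lon": lon0 + cfg.cell_size * np.arange(nx),
                "year": ("time", year), "doy": ("time", doy)},
        attrs={"seed": cfg.seed, "season": "May 1 - September 30"},
    )
    return ds


def generate_station_series(cfg: SyntheticConfig, station_id: str) -> pd.DataFrame:
    """Daily MT/RH series for one declared station, May–September only.

    Station streams are independent of the grid and of each other; each is
    seeded from ``(cfg.seed, station index)`` so adding stations never
    perturbs existing ones.
    """
    cfg.validate()
    ids = [s.station_id for s in cfg.stations]
    if station_id not in ids:
        raise KeyError(f"unknown station {station_id!r}")
    st = cfg.stations[ids.index(station_id)]
    rng = np.random.default_rng([cfg.seed, 7919, ids.index(station_id)])
    mt, rh = _background(cfg, rng, ())
    eps = [e for e in cfg.episodes if e.target == station_id]
    if eps:
        _inject(cfg, mt, rh, eps)
    dates = pd.DatetimeIndex(np.concatenate(
        [season_dates(y).values for y in cfg.year_list]))
    return pd.DataFrame({
        "station_id": station_id, "lon": st.lon, "lat": st.lat,
        "elev": st.elevation, "date": dates, "mt": mt, "rh": rh,
    })


def truth_catalog(cfg: SyntheticConfig) -> list[EpisodeTruth]:
    """Injected episodes as ground truth, merged and sorted.

    Episodes on the same target and year whose day ranges overlap or abut
    are merged into one record spanning their union (the detector can only
    ever see the union as a single run); the merged exceedance is the
    minimum of the parts (the margin every union day still guarantees).
    Sorted by (year, start, target).
    """
    cfg.validate()
    by_key: dict[tuple, list[EpisodeTruth]] = {}
    for ep in cfg.episodes:
        key = (str(ep.target), ep.year)
        by_key.setdefault(key, []).append(ep)
    merged: list[EpisodeTruth] = []
    for eps in by_key.values():
        eps = sorted(eps, key=lambda e: e.start)
        cur = eps[0]
        for ep in eps[1:]:
            if ep.start <= cur.stop:  # overlap or abut -> one run
                stop = max(cur.stop, ep.stop)
                cur = replace(cur, duration=stop - cur.start,
                              exceedance=min(cur.exceedance, ep.exceedance))
            else:
                merged.append(cur)
                cur = ep
        merged.append(cur)
    return sorted(merged, key=lambda e: (e.year, e.start, str(e.target)))


# -- configuration files ----------------------------------------------------

def save_config(cfg: SyntheticConfig, path) -> None:
    """Write a config as YAML (round-trips through :func:`load_config`)."""
    doc = {
        "seed": cfg.seed, "shape": list(cfg.shape),
        "cell_size": cfg.cell_size, "origin": list(cfg.origin),
        "years": list(cfg.years), "baseline_temp": cfg.baseline_temp,
        "seasonal_amplitude": cfg.seasonal_amplitude,
        "anomaly_rho": cfg.anomaly_rho, "anomaly_sd": cfg.anomaly_sd,
        "humidity_mean": cfg.humidity_mean, "humidity_sd": cfg.humidity_sd,
        "humidity_coupling": cfg.humidity_coupling,
        "episode_boost": cfg.episode_boost, "guard_days": cfg.guard_days,
        "guard_drop": cfg.guard_drop, "smoothing_sigma": cfg.smoothing_sigma,
        "enforce_margin": cfg.enforce_margin,
        "threshold_min_samples": cfg.threshold_min_samples,
        "stations": [{"station_id": s.station_id, "lon": s.lon,
                      "lat": s.lat, "elevation": s.elevation}
                     for s in cfg.stations],
        "episodes": [{"target": (ep.target if isinstance(ep.target, str)
                                 else list(ep.target)),
                      "year": ep.year, "start": ep.start,
                      "duration": ep.duration, "exceedance": ep.exceedance,
                      "mt_boost": ep.mt_boost, "rh_boost": ep.rh_boost}
                     for ep in cfg.episodes],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    """Read a YAML config written by :func:`save_config` (or by hand)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    stations = [StationSpec(**s) for s in doc.pop("stations", [])]
    episodes = []
    for e in doc.pop("episodes", []):
        tgt = e["target"]
        e["target"] = tgt if isinstance(tgt, str) else tuple(tgt)
        episodes.append(EpisodeTruth(**e))
    for key in ("shape", "origin", "years"):
        if key in doc:
            doc[key] = tuple(doc[key])
    cfg = SyntheticConfig(stations=stations, episodes=episodes, **doc)
    cfg.validate()
    return cfg
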