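# heathazard

Heatwave detection and hazard assessment on gridded daily climate data.

Summer heatwaves are usually defined not by temperature alone but by an
apparent-heat metric that folds in humidity, exceedance of a *locally
calibrated* threshold, and persistence over consecutive days. `heathazard`
implements such a pipeline for extended-summer (May 1 – September 30) stacks
of daily maximum temperature (MT, °C) and mean relative humidity (RH, %),
producing annual heatwave indicators, a normalized composite hazard surface,
trend and relative-change diagnostics, a natural-breaks spatiotemporal
typology, and zonal rankings. It is aimed at climate-impact and
environmental-health analysts who need a tested, reproducible implementation
rather than one-off scripts.

## The model

**Torridity index.** Daily apparent heat, on a dimensionless
Fahrenheit-like scale:

```
TI = 1.8·MT + 32 − 0.55·(1.8·MT − 26)·f(RH)
f(RH) = 1 − 0.6        if RH ≤ 60 %
f(RH) = 1 − RH/100     if RH > 60 %
```

**Local threshold TI′.** Per pixel, pool every day (all years) with
MT > 33 °C, compute their TIs, and take the 50th quantile with the
plotting-position rule `j = int(p·n + (1+p)/3)`, `γ = p·n + (1+p)/3 − j`,
`Q = (1−γ)·X(j) + γ·X(j+1)`. Days with TI ≥ TI′ are *hot days*.

**Heat index.** Each hot day is graded with a persistence-aware score.
With Δ = TI − TI′ for the current day, Δᵢ for the i-th immediately
preceding consecutive hot day, and N such days:

```
HI = 1.2·Δ + 0.35·Σ_{i=1..N} Δᵢ/i + 0.15·Σ_{i=1..N−1} 1/(i+1)
```

**Heatwave.** A run of ≥ 3 consecutive hot days whose event index HWI (the
mean of the run's daily HI; the run sum is available as a mode) is ≥ 2.8.
Per pixel and year this yields HWF (event count), HWMHI (max daily HI) and
HWMD (longest duration). Each indicator is normalized by its single maximum
over the whole space-time domain and the hazard is their equal-weight mean,
so `hazard ∈ [0, 1]`; AH is its multi-year mean. Trends are per-pixel OLS
slopes with a two-sided t-test; relative change is
`RC = (mean(last 5 yr) − mean(first 5 yr)) / mean(full period)`. AH and its
trend are each split into five Fisher–Jenks classes and crossed into four
categories (high & rapidly increasing / high & not increasing / low &
increasing / others); zones are ranked by mean AH and by trend slope.

A synthetic-climate generator (seasonal half-sine + AR(1) anomalies +
humidity coupled to the temperature anomaly) injects heat episodes with a
ground-truth catalog, so detection can be verified exactly.

## Worked example

```python
import numpy as np
from heathazard import (SyntheticConfig, EpisodeTruth, generate_grid,
                        ti_threshold, torridity_index, heat_index_field,
                        detect_events_grid, annual_indicators, HazardScorer,
                        average_hazard, linear_trend)

cfg = SyntheticConfig(seed=42, shape=(4, 4), years=(1990, 2019),
                      episodes=[EpisodeTruth(target=(2, 1), year=2010,
                                             start=60, duration=8)])
ds = generate_grid(cfg)
thr, n_hot, valid = ti_threshold(ds.mt.values, ds.rh.values)
ti = torridity_index(ds.mt.values, ds.rh.values)
hi, _ = heat_index_field(ti, thr, season_id=ds.year.values)
events = detect_events_grid(ti, hi, thr, ds.year.values)
ind = annual_indicators(events, cfg.year_list, shape=cfg.shape)
hz = HazardScorer().fit_transform({k: ind[k] for k in ("hwf", "hwmhi", "hwmd")})
ah = average_hazard(hz)
tr = linear_trend(hz, np.array(cfg.year_list))
```

This prints (via the obvious `print` statements):

```
grid: 4590 daily layers over 30 summers
TI' at pixel (2,1): 86.43 from 209 hot samples
detected 47 heatwave events
injected episode recovered: year=2010 start=60 duration=8 HWI=28.28 maxHI=37.43
AH at (2,1): 0.048 (grid mean 0.053); trend slope +0.0025/yr (p=0.56)
```

4590 layers is 30 summers × 153 days. The pixel's threshold (TI′ = 86.43)
comes from its 209 days above 33 °C. Besides the injected 8-day episode —
recovered with its exact year, start and duration — the detector finds 46
natural background heatwaves across the 16 pixels. The AH values are small
because hazard is normalized by the domain-wide indicator maxima, which the
strong injected episode sets; the trend p-value shows the background has no
significant drift.

The same flow is available from the shell:

```bash
heathazard simulate cfg.yaml --out grid.nc --truth truth.csv
heathazard threshold grid.nc --out thr.nc
heathazard detect grid.nc --threshold thr.nc --events events.csv --indicators annual.nc
heathazard hazard annual.nc --out hazard.nc
heathazard trend hazard.nc --out trend.nc
heathazard classify hazard.nc trend.nc --out classes.nc
heathazard zonal hazard.nc --zones zones.geojson --out zones.csv
```

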