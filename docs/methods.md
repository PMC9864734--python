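# Methods

## Torridity index and its humidity branches

The torridity index converts daily maximum temperature MT (°C) and mean
relative humidity RH (%) into a single apparent-heat value,

TI = 1.8·MT + 32 − 0.55·(1.8·MT − 26)·f(RH),

with f = 0.4 for RH ≤ 60 % and f = 1 − RH/100 above. RH enters as a
fraction: with RH as a raw percentage the humid branch would produce large
negative factors and absurd TI values. The two branches agree at RH = 60 %,
so TI is continuous; it is strictly increasing in MT everywhere and, for
MT > 26/1.8 ≈ 14.4 °C, increasing in RH on the humid branch. Although the
1.8/+32 structure gives Fahrenheit-like magnitudes, TI is treated as a
dimensionless index throughout.

## Local threshold TI′

TI′ is the 50th quantile of TI over all days with MT > 33 °C at a location,
pooled across every year of the record — a single fixed threshold per pixel,
which is what makes hazard values comparable across years. The quantile uses
the plotting-position rule j = int(p·n + (1+p)/3), γ = p·n + (1+p)/3 − j,
Q = (1−γ)X(j) + γX(j+1) on the ascending sample (1-based). The rule gives no
boundary prescription, so the package clamps symmetrically: j ≥ n returns
X(n), j < 1 returns X(1), both with γ = 0. Pixels with fewer than
`min_samples` (default 10) pooled hot days get no threshold — a median of a
handful of extremes is unstable — and are flagged invalid, never
zero-filled; they are excluded from detection.

## Heat index

On a hot day (TI ≥ TI′; the ≥ convention means a tie counts as hot, a
measure-zero case on continuous data), with Δ the day's exceedance, Δᵢ the
exceedance of the i-th immediately preceding consecutive hot day and N the
number of such days,

HI = 1.2·Δ + 0.35·Σ_{i=1..N} Δᵢ/i + 0.15·Σ_{i=1..N−1} 1/(i+1).

The lag index runs backwards from the current day (nᵈᵢ = i), and N counts
only the unbroken hot-day prefix: lag terms never cross a non-hot day, a
season edge, or a year boundary. The third summand carries no temperature
factor — it is a pure persistence bonus, equal to 0.15·(H_N − 1) with H the
harmonic numbers — and is implemented exactly in that form. The first hot
day of any run therefore has HI = 1.2·Δ exactly.

## Events and annual indicators

A heatwave is a maximal run of ≥ 3 consecutive hot days within one May –
September window whose HWI passes 2.8. HWI defaults to the **mean** of the
run's daily HI: 2.8 is a daily-grade cutoff, so only the mean keeps the
event filter on the same scale; the run **sum** (which equals N × mean) is
available as `hwi_mode="sum"`. Events belong to the calendar year they start
in. Per pixel-year the indicators are HWF (event count), HWMHI (maximum
daily HI over the year's events) and HWMD (longest duration); all zero when
no event occurs.

## Hazard, trends, relative change

Each indicator is divided by its **single domain-wide maximum** (all pixels,
all years); hazard is the equal-weight mean of the three normalized
indicators, hence in [0, 1], reaching 1 only where all three maxima coincide
in one pixel-year. A per-pixel normalization is available
(`HazardScorer(scope="pixel")`) but the global default is what keeps maps
comparable across regions and years. An all-zero indicator contributes 0
everywhere (0/0 guarded). AH is the multi-year mean of hazard.

Trends are per-pixel OLS fits of an annual series on the year, with a
two-sided t-test on the slope (α = 0.05 by default, no autocorrelation
correction). Degenerate cases are pinned explicitly: an exactly constant
series gets slope 0, R² 0, p 1; an exact non-flat line (zero residual
error) gets p 0.

Relative change RC = (mean over the last five years − mean over the first
five years) / full-period mean; it is scale-invariant, undefined (NaN) when
the full-period mean is zero, and RC > 0.8 is flagged as a sharp increase.
Group-wise RC (per region and/or month) averages the indicator within each
group-year first and then applies the formula to that annual series.

## Classification and zoning

Natural breaks are computed with the exact Fisher–Jenks dynamic program
(O(k·n²) with prefix sums), not the Jenks–Caspall heuristic, so the
partition provably minimizes within-class squared deviation and is
deterministic. Cuts are the maxima of the lower classes; intervals are
right-closed (a value equal to a cut joins the lower class) and the lowest
class is unbounded below. Five classes are fitted to AH (low … high) and
five to the trend slope (decreased … increased). Temporal breaks are fitted
on pixels passing the significance mask, and non-significant pixels are
labelled "basically unchanged"; when fewer than k distinct significant
slopes exist the breaks fall back to all finite slopes.

The four-way typology crosses the two label sets: {high, medium-high} ×
{increased, slightly increased} → category 1 (high & rapidly increasing);
the remaining {high, medium-high} cells → category 2; {middle, medium-low,
low} × {increased, slightly increased} → category 3 (the "middle" band is
included on the low side, matching the breadth of that category); everything
else → category 4. The exact band-to-category assignment is partly a design
choice, so the table is overridable.

Zonal statistics use a pixel-center-in-polygon rule (simple and
reproducible at fine grid resolution), report each zone's mean AH over valid
covered pixels and the OLS trend of the zone-mean annual hazard, and rank
zones descending by AH and by slope with ties broken by zone id; zones
without valid pixels are flagged and excluded from ranking.

## Validation metrics

For predicted/true pairs grouped into day, month or year units: MAE,
RMSE (≥ MAE always), a truth-on-prediction regression (true values on
predictions; noise on the predictions attenuates this slope slightly below
1), and max–min normalized NMAE/NRMSE computed **across the comparison set
of units within each variable**, so the best unit scores 0 and the worst 1.

## Synthetic climate: what it emulates and what it does not

The generator emulates the statistical shape of an extended-summer record:
a smooth seasonal cycle (half-sine over the 153-day window, always 153 days
regardless of leap years), AR(1) day-to-day temperature anomalies (heat
builds across consecutive days, which the HI lag terms reward), and humidity
as a clipped Gaussian linearly coupled to the temperature anomaly so both
dry-heat and humid-heat regimes are reachable. Defaults — baseline 22 °C,
amplitude 8 °C (peak ≈ 30 °C), anomaly σ 2.5 °C with ρ = 0.6, RH 65 ± 10 %
with −1.5 %/°C coupling — describe a warm-temperate summer in which a
realistic minority of days exceed the 33 °C hot-sample cutoff, every pixel
acquires a stable TI′ (hundreds of pooled samples over 30 years), and
natural background heatwaves occur alongside injected ones.

Episodes add a temperature plateau (default +12 °C) on their target days
rather than overwriting, so the background is bit-identical with and
without injection at the same seed. Two construction details make the truth
catalog *exactly* recoverable: (1) one flanking day on each side of an
episode is cooled (default −10 °C) so the injected run is the maximal hot
run and cannot be extended by a warm background day; (2) after injection
the pixel's eventual TI′ is recomputed and any episode day whose TI falls
short of TI′ + `exceedance` (default 2 index units) is lifted using the
exact inverse of the TI formula, iterated to a fixed point (≤ 6 rounds —
lifting episode days can nudge the pooled median, but it is bounded by the
background hot samples, so the loop settles immediately in practice).
Overlapping or abutting episodes on one target merge into a single truth
record spanning their union, with the merged margin taken as the minimum of
the parts (the guarantee every union day still satisfies).

What the generator does **not** emulate: spatial correlation (pixels are
independent; an optional Gaussian smoothing kernel is the only spatial
structure), topography and coastline effects, humidity autocorrelation,
multi-variable extremes beyond the linear MT–RH coupling, and any
station-network or interpolation error structure. Passing recovery tests
therefore demonstrates the correctness of the detection logic, not the
behaviour of the pipeline under realistic spatial error fields.

## Problem sizes and numerical choices

The test-suite and acceptance studies use a 20×20 grid over 30 summers
(4590 daily layers, 1.8 M cells) with 50 true episodes and 30 short decoys
— small enough to run in seconds while exercising every code path,
including natural background events. Exhaustive oracle checks enumerate all
3002 sorted multisets of length ≤ 10 over a 5-symbol alphabet for the
quantile (sorting makes multisets a complete cover of all sequences), all
2¹² binary masks for run detection, and 1000 sampled length ≤ 12 sequences
against an exhaustive-search Fisher–Jenks oracle. Monte-Carlo calibration
uses 500 replicates for slope recovery and 2000 for the null rejection rate
(binomial half-width ±0.01 at α = 0.05).

Tolerances: float comparisons in tests use pytest defaults (rel 1e-6)
except where an oracle is exact (1e-9). Thresholds are NaN where invalid
and every downstream stage propagates that mask; hazard of a pixel with no
events is exactly 0, not NaN.

## Known limitations

* The HI persistence bonus is temperature-free by construction; if a
  temperature-weighted variant is ever wanted it is a one-line change in
  `_run_heat_index`, but the published form is what is implemented.
* No autocorrelation correction in trend tests; with strongly autocorrelated
  annual series the significance mask is optimistic.
* GeoJSON is the only zone format (no shapefile reader); NetCDF I/O is
  classic-format (netCDF3) via xarray's scipy engine.
* The Fisher–Jenks DP is exact but quadratic in the number of values; for
  rasters beyond ~10⁵ valid pixels, classify a subsample or pre-bin.
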