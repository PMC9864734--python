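"""Synthetic climate generator: calendar, determinism, injection, truth."""

import numpy as np
import pytest

from heathazard.indices import ti_threshold, torridity_index
from heathazard.synthetic import (
    SEASON_DAYS,
    EpisodeTruth,
    StationSpec,
    SyntheticConfig,
    generate_grid,
    generate_station_series,
    load_config,
    save_config,
    truth_catalog,
)


def interval_union(spans):
    """Brute-force union of [start, stop) integer intervals."""
    days = sorted({d for a, b in spans for d in range(a, b)})
    out, cur = [], None
    for d in days:
        if cur and d == cur[1]:
            cur[1] = d + 1
        else:
            cur = [d, d + 1]
            out.append(cur)
    return [(a, b) for a, b in out]


class TestCalendar:
    def test_30_year_stack_has_4590_layers(self):
        cfg = SyntheticConfig(seed=0, shape=(1, 1), years=(1990, 2019))
        assert generate_grid(cfg).sizes["time"] == 4590

    def test_each_year_contributes_153_layers(self):
        cfg = SyntheticConfig(seed=0, shape=(1, 1), years=(1999, 2002))
        ds = generate_grid(cfg)
        _, counts = np.unique(ds["year"].values, return_counts=True)
        assert (counts == SEASON_DAYS).all()  # leap year 2000 included

    def test_one_year_station_series_has_153_records(self):
        cfg = SyntheticConfig(seed=0, years=(1993, 1993),
                              stations=[StationSpec("s1", 110.0, 30.0)])
        assert len(generate_station_series(cfg, "s1")) == 153

    def test_30_year_station_series_has_4590_records(self):
        cfg = SyntheticConfig(seed=0, years=(1990, 2019),
                              stations=[StationSpec("s1", 110.0, 30.0)])
        assert len(generate_station_series(cfg, "s1")) == 4590


class TestDeterminismAndBounds:
    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(seed=7, shape=(3, 2), years=(2000, 2002))
        a, b = generate_grid(cfg), generate_grid(cfg)
        assert np.array_equal(a["mt"].values, b["mt"].values)
        assert np.array_equal(a["rh"].values, b["rh"].values)

    def test_different_seed_differs(self):
        base = dict(shape=(2, 2), years=(2000, 2000))
        a = generate_grid(SyntheticConfig(seed=1, **base))
        b = generate_grid(SyntheticConfig(seed=2, **base))
        assert not np.array_equal(a["mt"].values, b["mt"].values)

    @pytest.mark.parametrize("seed", [0, 5, 99])
    def test_rh_bounded_mt_finite(self, seed):
        cfg = SyntheticConfig(seed=seed, shape=(2, 2), years=(2000, 2001))
        ds = generate_grid(cfg)
        rh = ds["rh"].values
        assert (rh >= 0).all() and (rh <= 100).all()
        assert np.isfinite(ds["mt"].values).all()

    def test_noise_free_limit_is_pure_sinusoid(self):
        cfg = SyntheticConfig(seed=0, shape=(2, 2), years=(2000, 2000),
                              anomaly_sd=1e-12, humidity_coupling=0.0)
        ds = generate_grid(cfg)
        d = np.arange(SEASON_DAYS)
        expected = (cfg.baseline_temp + cfg.seasonal_amplitude
                    * np.sin(np.pi * (d + 0.5) / SEASON_DAYS))
        assert np.allclose(ds["mt"].values[:, 0, 0], expected, atol=1e-9)


class TestValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(shape=(0, 3)).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(years=(2005, 2000)).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(anomaly_sd=0.0).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(episodes=[EpisodeTruth((0, 0), 1990, 150, 10)],
                            years=(1990, 1990)).validate()

    def test_unknown_station_lookup_error(self):
        cfg = SyntheticConfig(stations=[StationSpec("s1", 0, 0)])
        with pytest.raises(KeyError):
            generate_station_series(cfg, "nope")


class TestEpisodes:
    def test_injection_strictly_raises_target_days(self):
        ep = EpisodeTruth(target="s1", year=2000, start=50, duration=5)
        base_kw = dict(seed=3, years=(2000, 2000),
                       stations=[StationSpec("s1", 110, 30)])
        plain = generate_station_series(SyntheticConfig(**base_kw), "s1")
        boosted = generate_station_series(
            SyntheticConfig(episodes=[ep], **base_kw), "s1")
        sel = slice(50, 55)
        assert (boosted["mt"].values[sel] > plain["mt"].values[sel]).all()

    def test_grid_episode_block_elevated(self, demo_config, demo_grid):
        ep = demo_config.episodes[0]
        iy, ix = ep.target
        y0 = (ep.year - demo_config.years[0]) * SEASON_DAYS
        days = slice(y0 + ep.start, y0 + ep.stop)
        block = demo_grid["mt"].values[days, iy, ix]
        neighborhood = demo_grid["mt"].values[y0:y0 + SEASON_DAYS, iy, ix]
        assert block.min() > np.median(neighborhood) + 5

    def test_margin_invariant(self, demo_config, demo_grid):
        mt = demo_grid["mt"].values
        rh = demo_grid["rh"].values
        thr, _, valid = ti_threshold(mt, rh)
        for ep in truth_catalog(demo_config):
            iy, ix = ep.target
            assert valid[iy, ix]
            y0 = (ep.year - demo_config.years[0]) * SEASON_DAYS
            days = slice(y0 + ep.start, y0 + ep.stop)
            ti = torridity_index(mt[days, iy, ix], rh[days, iy, ix])
            assert (ti - thr[iy, ix] >= ep.exceedance - 1e-9).all()


class TestTruthCatalog:
    def test_empty_and_simple_counts(self):
        assert truth_catalog(SyntheticConfig()) == []
        eps = [EpisodeTruth((0, 0), 1995, 10, 3),
               EpisodeTruth((1, 1), 1996, 20, 4),
               EpisodeTruth((0, 1), 1997, 30, 5)]
        cat = truth_catalog(SyntheticConfig(shape=(2, 2), episodes=eps))
        assert len(cat) == 3
        assert [(e.year, e.start) for e in cat] == sorted(
            (e.year, e.start) for e in eps)

    def test_overlapping_episodes_merge_to_interval_union(self):
        eps = [EpisodeTruth((0, 0), 1995, 10, 5),   # days 10..14
               EpisodeTruth((0, 0), 1995, 13, 6),   # days 13..18 overlaps
               EpisodeTruth((0, 0), 1995, 19, 2),   # abuts at 19
               EpisodeTruth((0, 0), 1995, 40, 3)]   # separate
        cat = truth_catalog(SyntheticConfig(episodes=eps, shape=(1, 1)))
        got = [(e.start, e.start + e.duration) for e in cat]
        expected = interval_union([(10, 15), (13, 19), (19, 21), (40, 43)])
        assert got == expected


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path, demo_config):
        path = tmp_path / "cfg.yaml"
        save_config(demo_config, path)
        back = load_config(path)
        assert back == demo_config
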