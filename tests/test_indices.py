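"""Torridity index, threshold quantile, and heat-index mechanics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from heathazard.indices import (
    TorridityThreshold,
    heat_index_day,
    heat_index_field,
    invert_torridity,
    quantile_paper,
    ti_threshold,
    torridity_index,
)


def quantile_oracle(x, p):
    """Literal plotting-position quantile: sort, j = int(p·n + (1+p)/3),
    γ = fractional rest, interpolate X(j)..X(j+1) 1-based; clamp to the
    order statistics at both ends."""
    x = sorted(x)
    n = len(x)
    idx = p * n + (1 + p) / 3.0
    j = int(idx)
    if j >= n:
        return x[-1]
    if j < 1:
        return x[0]
    g = idx - j
    return (1 - g) * x[j - 1] + g * x[j]


class TestTorridityIndex:
    @pytest.mark.parametrize("mt,rh,expected", [
        (35.0, 40.0, 86.86),     # dry branch, hand-evaluated
        (26 / 1.8, 0.0, 58.0),   # humidity term vanishes when 1.8*MT = 26
        (26 / 1.8, 95.0, 58.0),
    ])
    def test_hand_values(self, mt, rh, expected):
        assert torridity_index(mt, rh) == pytest.approx(expected)

    def test_branch_continuity_at_60_percent(self):
        below = torridity_index(35.0, 60.0)
        eps = np.array([1e-3, 1e-6, 1e-9])
        above = torridity_index(35.0, 60.0 + eps)
        assert np.allclose(above, below, atol=1e-2)
        assert abs(above[-1] - below) < 1e-8

    def test_rh_domain_error(self):
        with pytest.raises(ValueError):
            torridity_index(30.0, 120.0)
        with pytest.raises(ValueError):
            torridity_index(30.0, -5.0)

    @given(mt=st.floats(-20, 50), dmt=st.floats(0.01, 10),
           rh=st.floats(0, 100))
    def test_strictly_increasing_in_mt(self, mt, dmt, rh):
        assert torridity_index(mt + dmt, rh) > torridity_index(mt, rh)

    @given(mt=st.floats(14.5, 50), rh=st.floats(60.01, 99),
           drh=st.floats(0.01, 1.0))
    def test_increasing_in_rh_on_humid_branch(self, mt, rh, drh):
        lo = torridity_index(mt, rh)
        hi = torridity_index(mt, min(rh + drh, 100.0))
        assert hi > lo

    @given(mt=st.floats(0, 45), rh=st.floats(0, 100))
    def test_inverse_roundtrip(self, mt, rh):
        ti = torridity_index(mt, rh)
        assert invert_torridity(ti, rh) == pytest.approx(mt, abs=1e-9)


class TestQuantile:
    @pytest.mark.parametrize("x,p,expected", [
        ([1, 2, 3, 4, 5], 0.5, 3.0),
        ([10, 20, 30, 40], 0.5, 25.0),
        ([80, 82, 84, 86, 88], 0.5, 84.0),
        ([7, 7, 7], 0.3, 7.0),  # constant sequence
    ])
    def test_hand_values(self, x, p, expected):
        assert quantile_paper(x, p) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_paper([], 0.5)

    @given(x=st.lists(st.floats(0, 100), min_size=1, max_size=10),
           p=st.sampled_from([0.1, 0.25, 0.5, 0.75, 0.9]))
    def test_matches_literal_oracle(self, x, p):
        assert quantile_paper(x, p) == pytest.approx(quantile_oracle(x, p))

    @given(x=st.lists(st.floats(0.1, 100), min_size=2, max_size=8),
           c=st.floats(0.1, 5))
    def test_positive_homogeneity(self, x, c):
        scaled = quantile_paper([c * v for v in x], 0.5)
        assert scaled == pytest.approx(c * quantile_paper(x, 0.5), rel=1e-9)


class TestThreshold:
    def test_known_hot_day_sequence(self):
        # craft MT at fixed RH=50 so the hot-sample TIs are 94,96,...,102
        target_ti = np.array([94.0, 96.0, 98.0, 100.0, 102.0])
        rh_val = 50.0
        mt_hot = invert_torridity(target_ti, rh_val)
        assert (mt_hot > 33).all()
        mt = np.concatenate([np.full(20, 25.0), mt_hot])[:, None]
        rh = np.full_like(mt, rh_val)
        thr, n, valid = ti_threshold(mt, rh, min_samples=5)
        assert valid[0]
        assert n[0] == 5
        assert thr[0] == pytest.approx(98.0)

    def test_no_hot_days_flagged_invalid(self):
        mt = np.full((50, 1), 20.0)
        rh = np.full((50, 1), 50.0)
        with pytest.warns(UserWarning):
            thr, n, valid = ti_threshold(mt, rh)
        assert not valid[0]
        assert np.isnan(thr[0])

    def test_estimator_transform_marks_hot_days(self, rng):
        mt = rng.uniform(25, 40, size=(300, 2, 2))
        rh = rng.uniform(30, 90, size=(300, 2, 2))
        est = TorridityThreshold(min_samples=5).fit(mt, rh)
        hot = est.transform(mt, rh)
        ti = torridity_index(mt, rh)
        expected = ti >= est.threshold_
        assert np.array_equal(hot[:, est.valid_], expected[:, est.valid_])


class TestHeatIndex:
    @pytest.mark.parametrize("prefix,tiprime,expected", [
        ([2.0], 0.0, 2.4),            # no preceding hot days
        ([1.0, 2.0], 0.0, 2.75),      # one preceding day
        ([1.0, 1.0, 1.0], 0.0, 1.8),  # two preceding days, unit exceedance
    ])
    def test_hand_values(self, prefix, tiprime, expected):
        assert heat_index_day(prefix, tiprime) == pytest.approx(expected)

    def test_non_hot_day_rejected(self):
        with pytest.raises(ValueError):
            heat_index_day([5.0, -1.0], 0.0)

    @given(deltas=st.lists(st.floats(0, 10), min_size=1, max_size=8),
           bump=st.floats(0.01, 5))
    def test_monotone_in_prior_day_ti(self, deltas, bump):
        if len(deltas) < 2:
            return
        base = heat_index_day(deltas, 0.0)
        raised = list(deltas)
        raised[0] += bump  # warm the earliest preceding day
        assert heat_index_day(raised, 0.0) >= base

    def test_persistence_bonus_depends_only_on_run_length(self):
        # a run at exactly the threshold isolates the third term
        for q in range(0, 6):
            hi = heat_index_day([0.0] * (q + 1), 0.0)
            harmonic_tail = sum(1.0 / (i + 1) for i in range(1, q))
            assert hi == pytest.approx(0.15 * harmonic_tail)

    def test_first_hot_day_rule(self, rng):
        for _ in range(20):
            delta = rng.uniform(0, 5)
            assert heat_index_day([delta], 0.0) == pytest.approx(1.2 * delta)


class TestHeatIndexField:
    def test_all_cool_pixel_fully_masked(self):
        ti = np.full((30, 1), 50.0)
        hi, lag = heat_index_field(ti, np.array([60.0]))
        assert np.isnan(hi).all()
        assert (lag == -1).all()

    def test_isolated_hot_day(self):
        ti = np.full((9, 1), 50.0)
        ti[4, 0] = 61.0
        hi, lag = heat_index_field(ti, np.array([60.0]))
        assert hi[4, 0] == pytest.approx(1.2)
        assert lag[4, 0] == 0
        assert np.isnan(np.delete(hi, 4)).all()

    def test_run_composes_single_day_formula(self):
        ti = np.array([50.0, 61.0, 61.0, 61.0, 50.0])[:, None]
        hi, _ = heat_index_field(ti, np.array([60.0]))
        assert hi[1, 0] == pytest.approx(heat_index_day([1.0], 0.0))
        assert hi[2, 0] == pytest.approx(heat_index_day([1.0, 1.0], 0.0))
        assert hi[3, 0] == pytest.approx(heat_index_day([1.0, 1.0, 1.0], 0.0))

    def test_lag_never_crosses_season_boundary(self):
        ti = np.full((6, 1), 61.0)
        seasons = np.array([0, 0, 0, 1, 1, 1])
        hi, lag = heat_index_field(ti, np.array([60.0]), season_id=seasons)
        assert list(lag[:, 0]) == [0, 1, 2, 0, 1, 2]

    def test_invalid_threshold_stays_masked(self):
        ti = np.full((10, 2), 80.0)
        hi, _ = heat_index_field(ti, np.array([60.0, np.nan]))
        assert np.isfinite(hi[:, 0]).all()
        assert np.isnan(hi[:, 1]).all()
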