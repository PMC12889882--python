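"""Evaluation: metric identities and oracles, category binning with the
round-then-bin rule, the dual split protocol, and stratified tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airsurf import (CATEGORY_BINS, PredictionSet, categorize,
                     compute_metrics, log_metrics, metrics_report,
                     quadrant_regions, seasonal_regional_mbe, split_protocol)


class TestComputeMetrics:
    def test_perfect_fit_identities(self, rng):
        y = rng.uniform(0, 50, 100)
        r2, rmse, mbe = compute_metrics(PredictionSet(y, y.copy()))
        assert (r2, rmse, mbe) == (1.0, 0.0, 0.0)

    def test_mean_predictor_gives_zero_r2(self, rng):
        y = rng.uniform(0, 50, 100)
        r2, _, _ = compute_metrics(PredictionSet(y, np.full(100, y.mean())))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_three_point_worked_case(self):
        r2, rmse, mbe = compute_metrics(
            PredictionSet([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]))
        assert rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert mbe == 0.0
        assert r2 == pytest.approx(0.0)

    def test_matches_naive_loop_oracle_to_1e10(self, rng):
        y = rng.uniform(0, 300, 1000)
        yh = y + rng.normal(0, 20, 1000)
        r2, rmse, mbe = compute_metrics(PredictionSet(y, yh))
        sq = sum((a - b) ** 2 for a, b in zip(y, yh))
        ybar = sum(y) / len(y)
        assert rmse == pytest.approx(np.sqrt(sq / len(y)), abs=1e-10)
        assert mbe == pytest.approx(sum(b - a for a, b in zip(y, yh)) / len(y),
                                    abs=1e-10)
        assert r2 == pytest.approx(
            1 - sq / sum((a - ybar) ** 2 for a in y), abs=1e-10)

    def test_constant_truth_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="constant"):
            r2, _, _ = compute_metrics(PredictionSet([5.0, 5.0], [4.0, 6.0]))
        assert r2 is None

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rmse_dominates_abs_mbe_and_r2_below_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        y = rng.uniform(0, 100, n)
        yh = rng.uniform(0, 100, n)
        r2, rmse, mbe = compute_metrics(PredictionSet(y, yh))
        assert rmse >= abs(mbe) - 1e-12
        if r2 is not None:
            assert r2 <= 1.0 + 1e-12

    def test_log_mode_round_trips_linear_metrics(self, rng):
        """log(1+x) metrics on exp-transformed pairs equal linear metrics
        on the originals."""
        y = rng.uniform(0, 4, 200)
        yh = y + rng.normal(0, 0.5, 200)
        lin = compute_metrics(PredictionSet(y, yh))
        back = log_metrics(PredictionSet(np.expm1(y), np.expm1(np.abs(yh))))
        ylog = np.log1p(np.expm1(y))
        np.testing.assert_allclose(lin[1], compute_metrics(
            PredictionSet(ylog, yh))[1], atol=1e-9)
        assert back[1] == pytest.approx(
            compute_metrics(PredictionSet(y, np.abs(yh)))[1], abs=1e-9)


class TestCategorize:
    @pytest.mark.parametrize("value,expect", [
        (10.0, "Good"),
        (300.0, "Hazardous"),
        (12.04, "Good"),          # rounds to 12.0
        (12.06, "Moderate"),      # rounds to 12.1
        (35.44, "Moderate"),
        (35.45, "Unhealthy for Sensitive Groups"),
        (0.0, "Good"),
        (250.5, "Hazardous"),
    ])
    def test_round_then_bin(self, value, expect):
        assert categorize(value) == expect

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize(-0.1)

    def test_bins_cover_halfline(self):
        for v in np.linspace(0, 400, 4001):
            categorize(float(v))  # must never fall through

    def test_bins_ordered_nonoverlapping(self):
        for (_, _, hi), (_, lo, _) in zip(CATEGORY_BINS, CATEGORY_BINS[1:]):
            assert lo > hi


class TestSplitProtocol:
    def test_sizes_1000(self):
        test_idx, folds = split_protocol(1000, seed=0)
        assert len(test_idx) == 100
        assert all(len(f) == 90 for f in folds)

    def test_partition_properties(self):
        test_idx, folds = split_protocol(437, seed=5)
        all_idx = np.concatenate([test_idx] + folds)
        assert len(all_idx) == 437
        assert len(np.unique(all_idx)) == 437  # disjoint and exhaustive

    def test_seeded_determinism(self):
        a = split_protocol(200, seed=3)
        b = split_protocol(200, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        for fa, fb in zip(a[1], b[1]):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_protocol(10, seed=0)

    def test_station_blocked_split_keeps_groups_whole(self, rng):
        stations = np.repeat([f"S{i}" for i in range(30)], 20)
        test_idx, folds = split_protocol(600, seed=1, block_by=stations)
        parts = [test_idx] + folds
        all_idx = np.concatenate(parts)
        assert len(np.unique(all_idx)) == 600
        seen: dict[str, int] = {}
        for pi, part in enumerate(parts):
            for s in np.unique(stations[part]):
                assert seen.setdefault(s, pi) == pi  # group in one part only


class TestStratified:
    def _pset(self, rng, n=400, winter_bias=0.0):
        dates = pd.to_datetime("2020-01-01") + pd.to_timedelta(
            rng.integers(0, 365, n), unit="D")
        lon = rng.uniform(-110, -100, n)
        lat = rng.uniform(35, 45, n)
        y = rng.uniform(0, 30, n)
        yh = y.copy()
        months = pd.DatetimeIndex(dates).month
        winter = np.isin(months, (12, 1, 2))
        yh[winter] += winter_bias
        meta = pd.DataFrame({"date": dates,
                             "region": quadrant_regions(lon, lat, -105, 40)})
        return PredictionSet(y, yh, meta)

    def test_all_zero_when_perfect(self, rng):
        table = seasonal_regional_mbe(self._pset(rng))
        np.testing.assert_allclose(table.to_numpy(), 0.0, atol=1e-12)

    def test_winter_bias_shows_in_winter_column_only(self, rng):
        table = seasonal_regional_mbe(self._pset(rng, winter_bias=1.0))
        assert table.loc["Avg", "winter"] == pytest.approx(1.0)
        for s in ("spring", "summer", "autumn"):
            assert table.loc["Avg", s] == pytest.approx(0.0, abs=1e-12)

    def test_cells_match_groupby_oracle(self, rng):
        p = self._pset(rng, winter_bias=0.7)
        table = seasonal_regional_mbe(p)
        df = pd.DataFrame({"err": p.y_hat - p.y,
                           "region": p.meta.region,
                           "month": pd.DatetimeIndex(p.meta.date).month})
        season = df.month.map(lambda m: "winter" if m in (12, 1, 2) else
                              "spring" if m in (3, 4, 5) else
                              "summer" if m in (6, 7, 8) else "autumn")
        oracle = df.groupby([df.region, season]).err.mean()
        for (reg, seas), val in oracle.items():
            assert table.loc[reg, seas] == pytest.approx(val, abs=1e-12)

    def test_unassigned_region_bucket_warns(self, rng):
        p = self._pset(rng)
        p.meta.loc[0, "region"] = None
        with pytest.warns(UserWarning, match="unassigned"):
            table = seasonal_regional_mbe(p)
        assert "unassigned" in table.index

    def test_report_counts_conserve_n(self, rng):
        y = rng.uniform(0, 300, 500)
        yh = y + rng.normal(0, 10, 500)
        rep = metrics_report(PredictionSet(y, np.maximum(yh, 0.0)))
        assert rep.by_category["n"].sum() == 500
        assert rep.high["n"] == (y > 35).sum()
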