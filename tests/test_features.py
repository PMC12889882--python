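"""Feature pipeline: temporal encodings, NDVI assignment, the AOD
gap-filler, [-1,1] scaling, and masked sequence construction."""

import numpy as np
import pandas as pd
import pytest

from airsurf import (FusionConfig, MinMaxScaler, WorldConfig, assign_ndvi,
                     build_feature_table, encode_time, generate_world,
                     impute_aod, station_targets)
from airsurf.features import FEATURE_NAMES, SENTINEL, FeaturePipeline


class TestEncodeTime:
    def test_zero_angle_at_january_first(self):
        c_doy, s_doy, c_m, s_m, year = encode_time("2020-01-01")
        assert (c_doy, s_doy) == (1.0, 0.0)
        assert (c_m, s_m) == (1.0, 0.0)
        assert year == 2020.0

    def test_year_boundary_is_circularly_adjacent(self):
        a = np.array(encode_time("2020-12-31")[:2])
        b = np.array(encode_time("2021-01-01")[:2])
        c = np.array(encode_time("2021-07-01")[:2])
        assert np.linalg.norm(a - b) < np.linalg.norm(b - c)

    def test_doy_100_against_direct_trig(self):
        c, s, *_ = encode_time("2021-04-10")  # doy = 100
        assert c == pytest.approx(np.cos(2 * np.pi * 99 / 365))
        assert s == pytest.approx(np.sin(2 * np.pi * 99 / 365))

    def test_encodings_bounded(self):
        for d in pd.date_range("2019-01-01", "2021-12-31", freq="17D"):
            vals = encode_time(d)[:4]
            assert all(-1.0 <= v <= 1.0 for v in vals)


class TestAssignNdvi:
    dates = pd.DatetimeIndex(["2020-01-01", "2020-01-17", "2020-02-02"])

    def test_exact_match(self):
        assert assign_ndvi("2020-01-17", self.dates) == 1

    def test_nearer_layer_wins(self):
        # 7 days after layer 1, 9 days before layer 2
        assert assign_ndvi("2020-01-24", self.dates) == 1

    def test_tie_goes_to_earlier_layer(self):
        # exact midpoint: 8 days from each
        assert assign_ndvi("2020-01-25", self.dates) == 1


class TestScaler:
    def test_endpoint_mapping(self):
        s = MinMaxScaler().fit(np.array([[0.0], [10.0]]))
        got = s.transform(np.array([[0.0], [10.0], [5.0]]))[:, 0]
        np.testing.assert_allclose(got, [-1.0, 1.0, 0.0])

    def test_round_trip_identity(self, rng):
        X = rng.normal(size=(40, 6)) * rng.uniform(0.1, 100, 6)
        s = MinMaxScaler().fit(X)
        np.testing.assert_allclose(s.inverse_transform(s.transform(X)), X,
                                   atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        s = MinMaxScaler().fit(np.full((5, 2), 3.0))
        out = s.transform(np.full((4, 2), 3.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_out_of_range_not_clipped(self):
        s = MinMaxScaler().fit(np.array([[0.0], [10.0]]))
        assert s.transform(np.array([[20.0]]))[0, 0] == pytest.approx(3.0)
        assert s.transform(np.array([[-5.0]]))[0, 0] == pytest.approx(-2.0)


class TestImputeAod:
    def test_pass_through_when_no_gaps(self, daily_world):
        out = impute_aod(daily_world.covariates["aod_047"],
                         daily_world.covariates, daily_world.ndvi_layers)
        np.testing.assert_array_equal(out.values,
                                      daily_world.covariates["aod_047"].values)

    def test_output_has_no_missing(self, small_world):
        out = impute_aod(small_world.covariates["aod_047"],
                         small_world.covariates, small_world.ndvi_layers)
        assert not np.isnan(out.values).any()
        obs = ~np.isnan(small_world.covariates["aod_047"].values)
        np.testing.assert_array_equal(
            out.values[obs], small_world.covariates["aod_047"].values[obs])

    def test_all_missing_raises(self, daily_world):
        stack = daily_world.covariates["aod_047"].copy()
        stack.values[:] = np.nan
        with pytest.raises(ValueError):
            impute_aod(stack, daily_world.covariates, daily_world.ndvi_layers)

    def test_noiseless_linear_world_recovery(self):
        """With AOD an exact linear function of PM2.5, held-back true
        values are recovered to <20% of the AOD sd. The world emulates the
        fine-grained satellite product regime: cells small relative to the
        field's correlation range, persistent day-to-day structure, no
        white noise."""
        from datetime import date
        cfg = WorldConfig(grid_nx=14, grid_ny=14, cell_km=2.0,
                          spatial_range_km=120.0, ar1_rho=0.95,
                          seasonal_amp=6.0, field_sd=3.0, noise_sd=0.0,
                          n_days=60, n_stations=10, start_date=date(2020, 3, 1),
                          aod_noise_sd=0.0, aod_missing_rate=0.4, seed=21)
        w = generate_world(cfg, n_smoke_events=0)
        truth = (cfg.aod_intercept + cfg.aod_slope * w.true_pm25.values)
        filled = impute_aod(w.covariates["aod_047"], w.covariates,
                            w.ndvi_layers)
        gaps = w.aod_mask
        rmse = np.sqrt(np.mean((filled.values[gaps] - truth[gaps]) ** 2))
        assert rmse < 0.2 * np.nanstd(truth)


@pytest.fixture(scope="module")
def built(daily_world):
    locs = daily_world.stations.copy()
    locs["loc_id"] = locs["station_id"]
    table = build_feature_table(daily_world, locs,
                                fusion_config=FusionConfig())
    targets = station_targets(daily_world)
    pipe = FeaturePipeline().fit(table, targets)
    ds = pipe.build_sequences(table, targets)
    return table, targets, pipe, ds


class TestSequences:
    def test_feature_roster_has_21_entries(self, built):
        table, *_ = built
        assert list(table.columns) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 21

    def test_window_shape_and_full_mask(self, built):
        _, targets, _, ds = built
        assert ds.X.shape[1:] == (21, 21)
        assert len(ds) == len(targets)
        # daily world, daily reporting, no AOD gaps: nothing masked
        assert not ds.mask.any()

    def test_target_date_is_last_row_date(self, built):
        table, _, pipe, ds = built
        i = 3
        row = ds.meta.iloc[i]
        t_feats = table.loc[(row.loc_id, pd.Timestamp(row.date))]
        scaled = pipe.scaler.transform(t_feats.to_numpy()[None, :])[0]
        np.testing.assert_allclose(ds.X[i, -1], scaled, atol=1e-12)

    def test_early_targets_are_skipped_with_warning(self, built, caplog):
        table, targets, pipe, _ = built
        bad = targets.iloc[:2].copy()
        bad.loc[:, "date"] = table.index.get_level_values("date").min()
        import logging
        with caplog.at_level(logging.WARNING, logger="airsurf.features"):
            ds = pipe.build_sequences(table, bad)
        assert len(ds) == 0
        assert "precedes" in caplog.text

    def test_sentinel_fills_masked_rows(self, small_world):
        """1-in-3 reporting does not mask timesteps (grid covariates are
        present), but a day with neither fused feature nor AOD is masked
        and carries the sentinel in every column."""
        locs = small_world.stations.copy()
        locs["loc_id"] = locs["station_id"]
        table = build_feature_table(small_world, locs, impute=False,
                                    fusion_config=FusionConfig())
        targets = station_targets(small_world)
        pipe = FeaturePipeline().fit(table, targets)
        ds = pipe.build_sequences(table, targets)
        assert ds.mask.any()
        assert (ds.X[ds.mask] == SENTINEL).all()
        # raw AOD gaps on unmasked days were median-filled and flagged
        assert ds.filled is not None and ds.filled.any()
        assert not ds.filled[ds.mask].any()

    def test_refit_with_test_rows_changes_params(self, built):
        """Leakage tripwire: the scaler is train-split-only, so adding
        held-out rows with new extremes must move the fitted range."""
        table, targets, pipe, _ = built
        widened = targets.copy()
        widened.loc[widened.index[-1], "y"] = 1e4
        p2 = FeaturePipeline().fit(table, widened)
        assert p2.y_scaler.max_[0] != pipe.y_scaler.max_[0]
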