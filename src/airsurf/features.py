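"""Predictor assembly: the per-(location, day) feature roster, AOD
gap-filling, temporal encodings, [-1, 1] scaling, and masked 21-day
sequence construction.

The 21-entry feature vector comprises two AOD bands, six Daymet-style
meteorological surfaces, wind direction/velocity, the ordinal wildfire
smoke density (WSD), elevation, 16-day NDVI, the KNN-IDW fused station
feature, latitude/longitude, and five temporal encodings
(cos/sin day-of-year, cos/sin month, year).

Missing-data policy: a timestep is masked (all-or-nothing) when its
feature row is absent or when both the fused feature and AOD are missing;
partially missing entries within an unmasked day are filled with the
training-split median and flagged. Masked rows carry the sentinel -2.0
(outside the scaled range); the model consumes the boolean mask, never the
sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd
import xarray as xr

from .fusion import build_idw_feature
from .config import FusionConfig
from .world import World

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES", "SENTINEL", "encode_time", "assign_ndvi", "impute_aod",
    "MinMaxScaler", "SequenceDataset", "FeaturePipeline",
    "build_feature_table", "station_targets",
]

FEATURE_NAMES: list[str] = [
    "aod_047", "aod_055",
    "dayl", "prcp", "srad", "tmax", "tmin", "vp",
    "wind_th", "wind_vs",
    "wsd", "elevation", "ndvi", "idw_pm25",
    "lat", "lon",
    "cos_doy", "sin_doy", "cos_month", "sin_month", "year",
]

SENTINEL = -2.0


def encode_time(date) -> tuple[float, float, float, float, float]:
    """Cyclic encodings: zero angle at Jan 1 / January; 365-day year."""
    ts = pd.Timestamp(date)
    a_doy = 2 * np.pi * (ts.dayofyear - 1) / 365.0
    a_mon = 2 * np.pi * (ts.month - 1) / 12.0
    return (float(np.cos(a_doy)), float(np.sin(a_doy)),
            float(np.cos(a_mon)), float(np.sin(a_mon)), float(ts.year))


def assign_ndvi(date, ndvi_dates: pd.DatetimeIndex) -> int:
    """Index of the NDVI layer closest in time; ties go to the earlier layer."""
    if len(ndvi_dates) == 0:
        raise ValueError("empty NDVI series")
    deltas = np.abs((ndvi_dates - pd.Timestamp(date)).days)
    return int(np.argmin(deltas))  # argmin takes the first (earlier) on ties


def _aod_neighbor_predictors(vals: np.ndarray) -> list[np.ndarray]:
    """Spatiotemporal context for the gap filler: a same-day
    inverse-distance average of observed AOD cells plus the same cell's
    previous/next-day retrievals (NaN where unavailable; the booster
    handles missing values natively)."""
    from scipy.spatial import cKDTree

    T, ny, nx = vals.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    spatial = np.full((T, ny * nx), np.nan)
    for t in range(T):
        v = vals[t].ravel()
        obs = ~np.isnan(v)
        if obs.sum() < 4:
            continue
        tree = cKDTree(pts[obs])
        d, idx = tree.query(pts, k=min(6, int(obs.sum())))
        w = 1.0 / np.maximum(d, 1e-6)
        spatial[t] = (w * v[obs][idx]).sum(axis=1) / w.sum(axis=1)
    prev = np.full((T, ny * nx), np.nan)
    prev[1:] = vals[:-1].reshape(T - 1, -1)
    nxt = np.full((T, ny * nx), np.nan)
    nxt[:-1] = vals[1:].reshape(T - 1, -1)
    return [spatial, prev, nxt]


def impute_aod(aod_stack: xr.DataArray, covariates: xr.Dataset,
               ndvi_layers: xr.DataArray, random_state: int = 0,
               include_wsd: bool = True) -> xr.DataArray:
    """Fill AOD gaps with a gradient-boosted regressor.

    Trained on observed cell-days with predictors: meteorology, WSD,
    elevation, NDVI, lat/lon, temporal encodings, and spatiotemporal
    neighbor retrievals (same-day observed-cell average, previous/next-day
    same cell). Observed cells pass through unchanged; the returned stack
    has no missing values. ``include_wsd=False`` drops the smoke-density
    predictor (the whole-pipeline WSD ablation).
    """
    import lightgbm as lgb

    vals = aod_stack.values
    missing = np.isnan(vals)
    if not missing.any():
        return aod_stack.copy()
    if missing.all():
        raise ValueError("cannot impute an all-missing AOD stack")

    T, ny, nx = vals.shape
    dates = pd.DatetimeIndex(aod_stack["time"].values)
    met = ["dayl", "prcp", "srad", "tmax", "tmin", "vp", "wind_th", "wind_vs"]
    if include_wsd:
        met.append("wsd")
    cols = [covariates[v].values.reshape(T, -1) for v in met]
    cols.append(np.broadcast_to(covariates["elevation"].values.reshape(1, -1), (T, ny * nx)))
    ndvi_dates = pd.DatetimeIndex(ndvi_layers["ndvi_time"].values)
    ndvi_idx = [assign_ndvi(d, ndvi_dates) for d in dates]
    cols.append(np.stack([ndvi_layers.values[i].ravel() for i in ndvi_idx]))
    lat2, lon2 = np.meshgrid(aod_stack["y"].values, aod_stack["x"].values, indexing="ij")
    cols.append(np.broadcast_to(lat2.reshape(1, -1), (T, ny * nx)))
    cols.append(np.broadcast_to(lon2.reshape(1, -1), (T, ny * nx)))
    enc = np.array([encode_time(d) for d in dates])          # (T, 5)
    for j in range(5):
        cols.append(np.broadcast_to(enc[:, j:j + 1], (T, ny * nx)))
    cols.extend(_aod_neighbor_predictors(vals))
    Xfull = np.stack([c.reshape(-1) for c in cols], axis=1)
    yfull = vals.reshape(-1)
    obs = ~np.isnan(yfull)

    # single-threaded + deterministic: imputed values must be identical
    # across runs and machines, or every downstream model inherits noise
    model = lgb.LGBMRegressor(n_estimators=250, num_leaves=127,
                              learning_rate=0.1, random_state=random_state,
                              n_jobs=1, deterministic=True,
                              force_row_wise=True, verbose=-1)
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        model.fit(Xfull[obs], yfull[obs])
        filled = vals.copy().reshape(-1)
        filled[~obs] = model.predict(Xfull[~obs])
    out = aod_stack.copy()
    out.values = filled.reshape(T, ny, nx)
    return out


class MinMaxScaler:
    """Feature-wise affine map of the training range onto [-1, 1].

    x' = 2*(x - min)/(max - min) - 1. A constant feature maps to 0.
    Values outside the training range map outside [-1, 1] (no clipping).
    NaNs pass through untouched.
    """

    def __init__(self):
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = np.nanmin(X, axis=0)
        self.max_ = np.nanmax(X, axis=0)
        return self

    def _span(self) -> np.ndarray:
        span = self.max_ - self.min_
        return np.where(span == 0, 1.0, span)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = 2.0 * (X - self.min_) / self._span() - 1.0
        return np.where(self.max_ == self.min_, 0.0 * out, out)

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        return (Xs + 1.0) / 2.0 * self._span() + self.min_

    def to_dict(self) -> dict:
        return {"min": self.min_.tolist(), "max": self.max_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        s = cls()
        s.min_ = np.asarray(d["min"], dtype=float)
        s.max_ = np.asarray(d["max"], dtype=float)
        return s


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def build_feature_table(world: World, locations: pd.DataFrame,
                        idw: pd.DataFrame | None = None,
                        impute: bool = True,
                        fusion_config: FusionConfig | None = None,
                        include_wsd: bool = True) -> pd.DataFrame:
    """Long feature table, one row per (location, day).

    locations: loc_id, lon, lat, ix, iy (grid cell indices), and optionally
    station_id (for leave-target-out fusion). If ``idw`` is None the fused
    feature is computed here with ``fusion_config``.
    Returns a MultiIndex (loc_id, date) frame with FEATURE_NAMES columns
    (minus ``wsd`` when ``include_wsd`` is False).
    """
    cov = world.covariates
    aod47, aod55 = cov["aod_047"], cov["aod_055"]
    if impute and np.isnan(aod47.values).any():
        aod47 = impute_aod(aod47, cov, world.ndvi_layers, include_wsd=include_wsd)
        aod55 = impute_aod(aod55, cov, world.ndvi_layers, include_wsd=include_wsd)

    dates = world.dates
    ndvi_dates = pd.DatetimeIndex(world.ndvi_layers["ndvi_time"].values)
    ndvi_idx = np.array([assign_ndvi(d, ndvi_dates) for d in dates])
    enc = np.array([encode_time(d) for d in dates])          # (T, 5)

    if idw is None:
        cfg = fusion_config or FusionConfig()
        tgt = locations.loc[locations.index.repeat(len(dates)),
                            [c for c in ("loc_id", "lon", "lat", "station_id")
                             if c in locations.columns]].reset_index(drop=True)
        tgt["date"] = np.tile(dates.values, len(locations))
        idw = build_idw_feature(world.observations, tgt, cfg)

    idw = idw.copy()
    idw["date"] = pd.to_datetime(idw["date"])
    idw_map = idw.set_index(["loc_id", "date"])["idw_pm25"]

    frames = []
    T = len(dates)
    for _, loc in locations.iterrows():
        iy, ix = int(loc.iy), int(loc.ix)
        row = {
            "aod_047": aod47.values[:, iy, ix],
            "aod_055": aod55.values[:, iy, ix],
        }
        for v in ("dayl", "prcp", "srad", "tmax", "tmin", "vp",
                  "wind_th", "wind_vs"):
            row[v] = cov[v].values[:, iy, ix]
        if include_wsd:
            row["wsd"] = cov["wsd"].values[:, iy, ix]
        row["elevation"] = np.full(T, cov["elevation"].values[iy, ix])
        row["ndvi"] = world.ndvi_layers.values[ndvi_idx, iy, ix]
        row["idw_pm25"] = idw_map.reindex(
            pd.MultiIndex.from_product([[loc.loc_id], dates])).to_numpy()
        row["lat"] = np.full(T, loc.lat)
        row["lon"] = np.full(T, loc.lon)
        for j, name in enumerate(("cos_doy", "sin_doy", "cos_month",
                                  "sin_month", "year")):
            row[name] = enc[:, j]
        df = pd.DataFrame(row, index=pd.MultiIndex.from_product(
            [[loc.loc_id], dates], names=["loc_id", "date"]))
        frames.append(df)
    names = [f for f in FEATURE_NAMES if include_wsd or f != "wsd"]
    return pd.concat(frames)[names]


def station_targets(world: World, window: int = 21) -> pd.DataFrame:
    """Station-day samples usable as sequence targets (enough look-back)."""
    first_valid = world.dates[window - 1]
    obs = world.observations
    t = obs[pd.to_datetime(obs["date"]) >= first_valid].copy()
    t = t.rename(columns={"pm25": "y"})
    t["loc_id"] = t["station_id"]
    return t.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceDataset:
    """Scaled, masked 21-day windows with day-t targets."""

    X: np.ndarray                # (N, T, F) scaled, sentinel on masked rows
    mask: np.ndarray             # (N, T) True where the timestep is missing
    y: np.ndarray                # (N,) raw ug/m3
    y_scaled: np.ndarray         # (N,)
    meta: pd.DataFrame           # loc_id, lon, lat, date (day t)
    feature_names: list[str] = field(default_factory=list)
    filled: np.ndarray | None = None  # (N, T, F) True where median-filled

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "SequenceDataset":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(int)
        return SequenceDataset(self.X[idx], self.mask[idx], self.y[idx],
                               self.y_scaled[idx],
                               self.meta.iloc[idx].reset_index(drop=True),
                               self.feature_names,
                               None if self.filled is None else self.filled[idx])


class FeaturePipeline:
    """Train-split-fitted scaling + median fill + sequence assembly.

    ``fit`` sees only training targets: the scaler range, the per-feature
    medians used for partial-missingness fill, and the target scaler are
    all estimated from training day-t rows alone (a leakage tripwire test
    asserts that refitting with test rows changes the parameters).
    """

    def __init__(self, feature_names: list[str] | None = None, window: int = 21):
        self.feature_names = list(feature_names or FEATURE_NAMES)
        self.window = window
        self.scaler = MinMaxScaler()
        self.y_scaler = MinMaxScaler()
        self.medians: np.ndarray | None = None

    def fit(self, feature_table: pd.DataFrame, train_targets: pd.DataFrame
            ) -> "FeaturePipeline":
        rows = feature_table.reindex(pd.MultiIndex.from_arrays(
            [train_targets["loc_id"], pd.to_datetime(train_targets["date"])]))
        X = rows[self.feature_names].to_numpy(dtype=float)
        self.scaler.fit(X)
        self.medians = np.nanmedian(X, axis=0)
        self.y_scaler.fit(train_targets["y"].to_numpy(dtype=float)[:, None])
        return self

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return self.y_scaler.transform(np.asarray(y, float)[:, None])[:, 0]

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return self.y_scaler.inverse_transform(np.asarray(ys, float)[:, None])[:, 0]

    def build_sequences(self, feature_table: pd.DataFrame,
                        targets: pd.DataFrame) -> SequenceDataset:
        """One masked window per target row (columns loc_id, date, y).

        Targets whose window would cross the start of the record are
        skipped with a logged warning.
        """
        if self.medians is None:
            raise RuntimeError("pipeline not fitted")
        F = len(self.feature_names)
        W = self.window
        table = feature_table[self.feature_names]
        start = table.index.get_level_values("date").min()

        Xs, masks, fills, keep_rows = [], [], [], []
        for i, row in targets.iterrows():
            t0 = pd.Timestamp(row["date"])
            if t0 - pd.Timedelta(days=W - 1) < start:
                log.warning("target %s @ %s precedes day %d of the record; skipped",
                            row["loc_id"], t0.date(), W)
                continue
            win = pd.date_range(t0 - pd.Timedelta(days=W - 1), t0, freq="D")
            block = table.reindex(
                pd.MultiIndex.from_product([[row["loc_id"]], win])).to_numpy(dtype=float)
            absent = np.isnan(block).all(axis=1)
            aod_cols = [self.feature_names.index(c)
                        for c in ("aod_047", "aod_055") if c in self.feature_names]
            idw_col = self.feature_names.index("idw_pm25")
            no_signal = np.isnan(block[:, idw_col])
            if aod_cols:
                no_signal &= np.isnan(block[:, aod_cols]).all(axis=1)
            mask = absent | no_signal
            # median-fill partial missingness on unmasked rows; flag fills
            was_nan = np.isnan(block)
            fill = np.where(was_nan, self.medians[None, :], block)
            scaled = self.scaler.transform(fill)
            scaled[mask] = SENTINEL
            Xs.append(scaled)
            masks.append(mask)
            fills.append(was_nan & ~mask[:, None])
            keep_rows.append(i)

        meta = targets.loc[keep_rows].reset_index(drop=True)
        X = np.stack(Xs) if Xs else np.empty((0, W, F))
        mask = np.stack(masks) if masks else np.empty((0, W), dtype=bool)
        filled = np.stack(fills) if fills else np.empty((0, W, F), dtype=bool)
        y = meta["y"].to_numpy(dtype=float) if "y" in meta else np.full(len(meta), np.nan)
        y_scaled = self.scale_y(y) if len(y) else y
        return SequenceDataset(X, mask, y, y_scaled, meta, self.feature_names,
                               filled)

    def to_dict(self) -> dict:
        return {"feature_names": self.feature_names, "window": self.window,
                "scaler": self.scaler.to_dict(),
                "y_scaler": self.y_scaler.to_dict(),
                "medians": self.medians.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeaturePipeline":
        p = cls(d["feature_names"], d["window"])
        p.scaler = MinMaxScaler.from_dict(d["scaler"])
        p.y_scaler = MinMaxScaler.from_dict(d["y_scaler"])
        p.medians = np.asarray(d["medians"], dtype=float)
        return p
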