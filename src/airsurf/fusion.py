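"""KNN-IDW fusion of station measurements into a gridded feature.

For a target (location, day), the k nearest *reporting* stations by
haversine distance (k = 9 by default) are combined with weights
proportional to inverse distance, giving the "inverse distance weighted
PM2.5" predictor. Two modes:

- ``leave_target_out``: the target station's own same-day record is
  excluded, so the feature carries no information about the value being
  predicted (the leakage control used during training and evaluation).
- ``full``: all reporting stations are used (production surfaces).

Only stations reporting on the target date are candidates; days a station
skips are handled downstream by the sequence mask, not by temporal
borrowing here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FusionConfig

__all__ = ["NeighborSet", "haversine_km", "find_neighbors", "idw_estimate",
           "build_idw_feature"]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on WGS84 (spherical approximation)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float),
                                              np.asarray(lat1, float),
                                              np.asarray(lon2, float),
                                              np.asarray(lat2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class NeighborSet:
    """The k nearest reporting stations for one target, distance-sorted."""

    station_ids: list[str]
    distances_km: np.ndarray
    values: np.ndarray          # ug/m3
    weights: np.ndarray         # normalized, sum to 1
    underfilled: bool           # fewer than k candidates were available


def _idw_weights(distances_km: np.ndarray, power: float) -> np.ndarray:
    d = np.asarray(distances_km, dtype=float)
    zero = d <= 0.0
    if zero.any():
        # a collocated station determines the estimate outright
        w = np.zeros_like(d)
        w[np.argmax(zero)] = 1.0
        return w
    w = d ** (-power)
    return w / w.sum()


def find_neighbors(target_lon: float, target_lat: float,
                   day_observations: pd.DataFrame,
                   config: FusionConfig,
                   exclude_station_id: str | None = None) -> NeighborSet | None:
    """Nearest reporting stations for one target-day.

    ``day_observations`` holds one row per station reporting on the target
    date (columns station_id, lon, lat, pm25). Returns None when no
    candidate remains (the feature is marked missing downstream). Ties in
    distance are broken by station id so the result is deterministic.
    """
    obs = day_observations
    if exclude_station_id is not None:
        obs = obs[obs["station_id"] != exclude_station_id]
    if len(obs) == 0:
        return None
    d = haversine_km(target_lon, target_lat, obs["lon"].to_numpy(), obs["lat"].to_numpy())
    order = np.lexsort((obs["station_id"].to_numpy(), d))[: config.k]
    d_sel = d[order]
    values = obs["pm25"].to_numpy()[order]
    ids = obs["station_id"].to_numpy()[order].tolist()
    return NeighborSet(ids, d_sel, values, _idw_weights(d_sel, config.idw_power),
                       underfilled=len(obs) < config.k)


def idw_estimate(neighbors: NeighborSet | None) -> float:
    """Inverse-distance-weighted estimate; NaN marks a missing feature."""
    if neighbors is None or len(neighbors.values) == 0:
        return float("nan")
    return float(neighbors.weights @ neighbors.values)


def build_idw_feature(observations: pd.DataFrame, targets: pd.DataFrame,
                      config: FusionConfig) -> pd.DataFrame:
    """Vectorized KNN-IDW over many targets.

    observations: station_id, lon, lat, date, pm25.
    targets: lon, lat, date, and (in leave_target_out mode) an optional
    station_id column naming the target's own station to exclude.
    Returns targets + columns idw_pm25, n_neighbors, underfilled.
    """
    config.validate()
    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    targets = targets.copy()
    targets["date"] = pd.to_datetime(targets["date"])
    exclude = (targets["station_id"] if
               (config.mode == "leave_target_out" and "station_id" in targets)
               else pd.Series([None] * len(targets), index=targets.index))

    by_date = {d: g for d, g in obs.groupby("date")}
    est = np.full(len(targets), np.nan)
    n_nb = np.zeros(len(targets), dtype=int)
    under = np.zeros(len(targets), dtype=bool)
    for i, (_, row) in enumerate(targets.iterrows()):
        day = by_date.get(row["date"])
        if day is None:
            under[i] = True
            continue
        ns = find_neighbors(row["lon"], row["lat"], day, config,
                            exclude_station_id=exclude.iloc[i])
        if ns is None:
            under[i] = True
            continue
        est[i] = idw_estimate(ns)
        n_nb[i] = len(ns.values)
        under[i] = ns.underfilled
    out = targets.copy()
    out["idw_pm25"] = est
    out["n_neighbors"] = n_nb
    out["underfilled"] = under
    return out


def grid_idw_feature(observations: pd.DataFrame, lons: np.ndarray,
                     lats: np.ndarray, dates: pd.DatetimeIndex,
                     config: FusionConfig) -> np.ndarray:
    """Full-mode KNN-IDW for many targets at once (production surfaces).

    Returns an (n_dates, n_targets) array; NaN where no station reports.
    Matches the per-target path numerically: same distance function, the
    same (distance, station id) tie-break, and the same zero-distance rule.
    """
    config.validate()
    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    out = np.full((len(dates), len(lons)), np.nan)
    by_date = {d: g.sort_values("station_id") for d, g in obs.groupby("date")}
    for ti, d in enumerate(dates):
        day = by_date.get(pd.Timestamp(d))
        if day is None or len(day) == 0:
            continue
        ds = haversine_km(lons[:, None], lats[:, None],
                          day["lon"].to_numpy()[None, :],
                          day["lat"].to_numpy()[None, :])
        k = min(config.k, ds.shape[1])
        idx = np.argsort(ds, axis=1, kind="stable")[:, :k]
        d_sel = np.take_along_axis(ds, idx, axis=1)
        v_sel = day["pm25"].to_numpy()[idx]
        with np.errstate(divide="ignore"):
            w = d_sel ** (-config.idw_power)
        zero = d_sel <= 0.0
        rows0 = zero.any(axis=1)
        if rows0.any():
            w[rows0] = 0.0
            w[np.flatnonzero(rows0), np.argmax(zero[rows0], axis=1)] = 1.0
        out[ti] = (w * v_sel).sum(axis=1) / w.sum(axis=1)
    return out
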