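"""Evaluation machinery: R2 / RMSE / MBE, AQI-style concentration
categories, the dual validation protocol (10% held-out test + 10-fold
random CV), season x region MBE decomposition, the wildfire-smoke-density
ablation, and the point-to-point random-forest baseline.

Conventions: R2 = 1 - sum(y - yhat)^2 / sum(y - ybar)^2;
RMSE = sqrt(mean(y - yhat)^2); MBE = mean(yhat - y), positive meaning
systematic overestimation. The high-concentration stratum is ground truth
above 35 ug/m3, where wildfire-driven extremes dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "compute_metrics", "categorize", "CATEGORY_BINS", "split_protocol",
    "PredictionSet", "MetricsReport", "metrics_report",
    "seasonal_regional_mbe", "season_of", "quadrant_regions",
    "random_forest_baseline", "log_metrics",
]

# (name, lower, upper) in ug/m3 after rounding to one decimal
CATEGORY_BINS = [
    ("Good", 0.0, 12.0),
    ("Moderate", 12.1, 35.4),
    ("Unhealthy for Sensitive Groups", 35.5, 55.4),
    ("Unhealthy", 55.5, 150.4),
    ("Very Unhealthy", 150.5, 250.4),
    ("Hazardous", 250.5, np.inf),
]

SEASONS = {"spring": (3, 4, 5), "summer": (6, 7, 8),
           "autumn": (9, 10, 11), "winter": (12, 1, 2)}


@dataclass
class PredictionSet:
    """Paired truths/predictions with per-sample metadata."""

    y: np.ndarray
    y_hat: np.ndarray
    meta: pd.DataFrame | None = None   # date, lon, lat, region ...

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if self.y.shape != self.y_hat.shape:
            raise ValueError("y and y_hat must have equal length")

    def __len__(self):
        return len(self.y)


def compute_metrics(p: PredictionSet) -> tuple[float | None, float, float]:
    """(R2, RMSE, MBE). R2 is None (with a warning) for constant truth."""
    y, yh = p.y, p.y_hat
    if len(y) < 2:
        raise ValueError("need at least 2 pairs")
    rmse = float(np.sqrt(np.mean((y - yh) ** 2)))
    mbe = float(np.mean(yh - y))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant ground truth: R2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = 1.0 - float(np.sum((y - yh) ** 2)) / ss_tot
    return r2, rmse, mbe


def log_metrics(p: PredictionSet) -> tuple[float | None, float, float]:
    """Metrics on log(1 + x)-transformed pairs (for density-plot-style
    reporting of high concentrations)."""
    return compute_metrics(PredictionSet(np.log1p(p.y), np.log1p(p.y_hat), p.meta))


def categorize(pm25: float) -> str:
    """AQI-style category of a concentration, rounding to one decimal
    before binning (reconciling the gapped breakpoints, e.g. 12.0 vs 12.1)."""
    if pm25 < 0 or not np.isfinite(pm25):
        raise ValueError(f"PM2.5 must be finite and >= 0, got {pm25}")
    v = round(float(pm25), 1)
    for name, lo, hi in CATEGORY_BINS:
        if lo <= v <= hi:
            return name
    raise AssertionError("bins cover [0, inf)")  # pragma: no cover


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Overall and stratified scores for one model's predictions."""

    r2: float | None
    rmse: float
    mbe: float
    n: int
    by_category: pd.DataFrame | None = None
    by_season: pd.DataFrame | None = None
    by_region: pd.DataFrame | None = None
    high: dict = dc_field(default_factory=dict)   # >35 ug/m3 subset

    def to_dict(self) -> dict:
        d = {"r2": self.r2, "rmse": self.rmse, "mbe": self.mbe, "n": self.n,
             "high": self.high}
        for key in ("by_category", "by_season", "by_region"):
            df = getattr(self, key)
            if df is not None:
                d[key] = df.to_dict(orient="index")
        return d

    def render(self) -> str:
        lines = [f"n={self.n}  R2={'NA' if self.r2 is None else f'{self.r2:.3f}'}"
                 f"  RMSE={self.rmse:.3f}  MBE={self.mbe:+.3f} ug/m3"]
        if self.high:
            lines.append(f">35 ug/m3 subset: n={self.high['n']}"
                         f"  RMSE={self.high['rmse']:.3f}"
                         f"  MBE={self.high['mbe']:+.3f}")
        for label, df in (("category", self.by_category),
                          ("season", self.by_season),
                          ("region", self.by_region)):
            if df is not None and len(df):
                lines.append(f"-- by {label} --")
                lines.append(df.to_string())
        return "\n".join(lines)


def _strata_frame(y, y_hat, labels) -> pd.DataFrame:
    df = pd.DataFrame({"y": y, "y_hat": y_hat, "label": labels})
    rows = {}
    for name, g in df.groupby("label", sort=False, observed=True):
        err = g.y_hat - g.y
        rows[name] = {"n": len(g), "rmse": float(np.sqrt(np.mean(err ** 2))),
                      "mbe": float(err.mean())}
    return pd.DataFrame.from_dict(rows, orient="index")


def metrics_report(p: PredictionSet, high_threshold: float = 35.0) -> MetricsReport:
    """Full report: overall, per concentration category, per season and
    region (when the metadata carries date / region), and the
    high-concentration subset."""
    r2, rmse, mbe = compute_metrics(p)
    rep = MetricsReport(r2, rmse, mbe, len(p))
    cats = [categorize(v) for v in np.maximum(p.y, 0.0)]
    order = [c[0] for c in CATEGORY_BINS]
    by_cat = _strata_frame(p.y, p.y_hat, pd.Categorical(cats, categories=order))
    rep.by_category = by_cat.loc[[c for c in order if c in by_cat.index]]
    hi = p.y > high_threshold
    if hi.sum() >= 2:
        hr2, hrmse, hmbe = compute_metrics(PredictionSet(p.y[hi], p.y_hat[hi]))
        rep.high = {"n": int(hi.sum()), "r2": hr2, "rmse": hrmse, "mbe": hmbe}
    elif hi.any():
        err = p.y_hat[hi] - p.y[hi]
        rep.high = {"n": int(hi.sum()), "r2": None,
                    "rmse": float(np.sqrt(np.mean(err ** 2))),
                    "mbe": float(err.mean())}
    if p.meta is not None and "date" in p.meta:
        seasons = [season_of(d) for d in pd.to_datetime(p.meta["date"])]
        rep.by_season = _strata_frame(p.y, p.y_hat, seasons)
    if p.meta is not None and "region" in p.meta:
        rep.by_region = _strata_frame(p.y, p.y_hat, p.meta["region"].to_numpy())
    return rep


# ---------------------------------------------------------------------------
# Validation protocol
# ---------------------------------------------------------------------------

def split_protocol(n: int, seed: int, test_fraction: float = 0.1,
                   n_folds: int = 10,
                   block_by: np.ndarray | None = None
                   ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Random 10% held-out test set + 10 disjoint CV folds over the rest.

    Sample-random by default. ``block_by`` (e.g. station ids, one per
    sample) switches to a blocked split: whole groups are assigned to the
    test set and folds together, so no group straddles a boundary.
    Returns (test_idx, folds) where folds partition the remaining indices.
    """
    if n < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} samples")
    rng = np.random.default_rng(seed)
    if block_by is None:
        perm = rng.permutation(n)
        n_test = int(round(n * test_fraction))
        test_idx = np.sort(perm[:n_test])
        rest = perm[n_test:]
        folds = [np.sort(f) for f in np.array_split(rest, n_folds)]
        return test_idx, folds

    block_by = np.asarray(block_by)
    if len(block_by) != n:
        raise ValueError("block_by must have one label per sample")
    groups = rng.permutation(np.unique(block_by))
    n_test_g = max(1, int(round(len(groups) * test_fraction)))
    if len(groups) - n_test_g < n_folds:
        raise ValueError(f"need >= {n_folds} non-test groups for blocked folds")
    test_groups = set(groups[:n_test_g])
    rest_groups = np.array_split(groups[n_test_g:], n_folds)
    test_idx = np.flatnonzero(np.isin(block_by, list(test_groups)))
    folds = [np.flatnonzero(np.isin(block_by, g)) for g in rest_groups]
    return test_idx, folds


def season_of(date) -> str:
    m = pd.Timestamp(date).month
    for name, months in SEASONS.items():
        if m in months:
            return name
    raise AssertionError  # pragma: no cover


def quadrant_regions(lon: np.ndarray, lat: np.ndarray,
                     lon_mid: float, lat_mid: float) -> np.ndarray:
    """Default synthetic region partition: grid quadrants (NW/NE/SW/SE)."""
    ns = np.where(np.asarray(lat) >= lat_mid, "N", "S")
    ew = np.where(np.asarray(lon) >= lon_mid, "E", "W")
    return np.char.add(ns, ew)


def seasonal_regional_mbe(p: PredictionSet) -> pd.DataFrame:
    """Season x region MBE table with row and column averages.

    Metadata must carry ``date`` and ``region``; samples with a missing
    region are counted in an 'unassigned' bucket with a warning.
    """
    if p.meta is None or "date" not in p.meta or "region" not in p.meta:
        raise ValueError("seasonal_regional_mbe needs date and region metadata")
    region = p.meta["region"].astype(object).to_numpy().copy()
    missing = pd.isna(region)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} samples with no region -> 'unassigned'",
                      stacklevel=2)
        region[missing] = "unassigned"
    df = pd.DataFrame({
        "err": p.y_hat - p.y,
        "season": [season_of(d) for d in pd.to_datetime(p.meta["date"])],
        "region": region,
    })
    table = df.pivot_table(values="err", index="region", columns="season",
                           aggfunc="mean")
    season_order = [s for s in SEASONS if s in table.columns]
    table = table[season_order]
    table["Avg"] = table.mean(axis=1)
    table.loc["Avg"] = table.mean(axis=0)
    return table


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def random_forest_baseline(X_train: np.ndarray, y_train: np.ndarray,
                           X_eval: np.ndarray, seed: int = 0,
                           n_search: int = 8) -> np.ndarray:
    """Point-to-point random forest on day-t feature vectors.

    Hyperparameters come from a fixed-budget random search (trees, depth,
    min samples per leaf) scored by out-of-bag error; missing entries are
    median-filled from the training split.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.model_selection import ParameterSampler

    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    Xtr = np.where(np.isnan(X_train), med[None, :], X_train)
    Xev = np.where(np.isnan(X_eval), med[None, :], X_eval)

    grid = {"n_estimators": [100, 200, 300],
            "max_depth": [None, 8, 16, 24],
            "min_samples_leaf": [1, 2, 5]}
    best, best_score = None, -np.inf
    for i, params in enumerate(ParameterSampler(grid, n_iter=n_search,
                                                random_state=seed)):
        rf = RandomForestRegressor(random_state=seed + i, oob_score=True,
                                   bootstrap=True, n_jobs=1, **params)
        rf.fit(Xtr, y_train)
        if rf.oob_score_ > best_score:
            best, best_score = rf, rf.oob_score_
    return best.predict(Xev)
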