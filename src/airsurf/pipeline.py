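"""End-to-end experiment orchestration on a (synthetic or loaded) world.

Wires the stages together under the leakage rules: leave-target-out
fusion for the station feature, train-split-only scaler/median fitting,
and shared sample-level splits across every model being compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FusionConfig, ModelConfig, TrainConfig
from .features import (FEATURE_NAMES, FeaturePipeline, SequenceDataset,
                       build_feature_table, station_targets)
from .metrics import (MetricsReport, PredictionSet, metrics_report,
                      quadrant_regions, random_forest_baseline, split_protocol)
from .model import PM25SequenceModel
from .train import TrainResult, train
from .world import World

__all__ = ["prepare_station_data", "run_experiment", "cross_validate",
           "ablate_wsd", "compare_baselines", "ExperimentResult"]


def prepare_station_data(world: World, fusion_config: FusionConfig | None = None,
                         impute: bool = True
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Station-location feature table (leave-target-out fusion) + targets.

    Targets carry a quadrant region label for stratified reporting.
    """
    fusion_config = fusion_config or FusionConfig(mode="leave_target_out")
    locations = world.stations.rename(columns={}).copy()
    locations["loc_id"] = locations["station_id"]
    table = build_feature_table(world, locations, impute=impute,
                                fusion_config=fusion_config)
    targets = station_targets(world)
    targets["region"] = quadrant_regions(
        targets["lon"].to_numpy(), targets["lat"].to_numpy(),
        lon_mid=float(np.median(world.lon)), lat_mid=float(np.median(world.lat)))
    return table, targets


@dataclass
class ExperimentResult:
    report: MetricsReport                  # held-out test report
    predictions: PredictionSet             # held-out test predictions, ug/m3
    model: PM25SequenceModel
    pipeline: FeaturePipeline
    train_result: TrainResult
    val_report: MetricsReport | None = None
    splits: dict = field(default_factory=dict)


def _fit_and_score(table, targets, train_idx, val_idx, test_idx,
                   feature_names, widths, seed, model_overrides,
                   train_overrides, report_on: str = "test") -> ExperimentResult:
    pipe = FeaturePipeline(feature_names)
    pipe.fit(table, targets.iloc[train_idx])
    ds = pipe.build_sequences(table, targets)
    if len(ds) != len(targets):
        # windows too early were dropped; remap split indices
        kept = {t: i for i, t in enumerate(ds.meta.index)}
        raise RuntimeError("targets with insufficient look-back in split")

    overrides = dict(train_overrides or {})
    n_restarts = int(overrides.pop("n_restarts", 1))
    tcfg = TrainConfig(seed=seed, **overrides)
    model = tr = None
    for r in range(n_restarts):   # best-of-k inits, chosen on validation
        mcfg = ModelConfig(layer_widths=tuple(widths),
                           n_features=len(feature_names),
                           seed=seed + 1000 * r, **(model_overrides or {}))
        m = PM25SequenceModel(mcfg)
        t = train(m, ds.subset(train_idx), ds.subset(val_idx), tcfg)
        if tr is None or t.best_val_loss < tr.best_val_loss:
            model, tr = m, t

    def report_for(idx):
        sub = ds.subset(idx)
        y_hat = np.maximum(pipe.unscale_y(model.predict(sub.X, sub.mask)), 0.0)
        pset = PredictionSet(sub.y, y_hat, sub.meta)
        return metrics_report(pset), pset

    val_rep, _ = report_for(val_idx)
    report_idx = (np.concatenate([val_idx, test_idx])
                  if report_on == "heldout" else test_idx)
    test_rep, test_pset = report_for(report_idx)
    return ExperimentResult(test_rep, test_pset, model, pipe, tr, val_rep,
                            {"train": train_idx, "val": val_idx, "test": test_idx})


def run_experiment(world: World, widths=(16, 8, 8), seed: int = 0,
                   include_wsd: bool = True,
                   table: pd.DataFrame | None = None,
                   targets: pd.DataFrame | None = None,
                   model_overrides: dict | None = None,
                   train_overrides: dict | None = None,
                   report_on: str = "test") -> ExperimentResult:
    """Single-split experiment: 10% held-out test, first CV fold as
    validation, remaining folds as the training set. ``report_on``:
    "test" scores the 10% test set; "heldout" scores val + test (used by
    small studies whose strata would otherwise hold a handful of samples).
    """
    if table is None or targets is None:
        table, targets = prepare_station_data(world)
    names = [f for f in FEATURE_NAMES if include_wsd or f != "wsd"]
    test_idx, folds = split_protocol(len(targets), seed)
    val_idx = folds[0]
    train_idx = np.concatenate(folds[1:])
    return _fit_and_score(table, targets, train_idx, val_idx, test_idx,
                          names, widths, seed, model_overrides,
                          train_overrides, report_on)


def cross_validate(world: World, widths=(16, 8, 8), seed: int = 0,
                   n_folds: int = 10, include_wsd: bool = True,
                   train_overrides: dict | None = None) -> dict:
    """The full dual protocol: 10-fold CV over the 90%, fold-averaged
    validation metrics, and test metrics from the best-validation fold's
    model applied to the 10% held-out set."""
    table, targets = prepare_station_data(world)
    names = [f for f in FEATURE_NAMES if include_wsd or f != "wsd"]
    test_idx, folds = split_protocol(len(targets), seed, n_folds=n_folds)
    results = []
    for i in range(n_folds):
        val_idx = folds[i]
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        results.append(_fit_and_score(table, targets, train_idx, val_idx,
                                      test_idx, names, widths, seed,
                                      None, train_overrides))
    val_rmses = [r.val_report.rmse for r in results]
    best = int(np.argmin(val_rmses))
    return {
        "val_mean": {"r2": float(np.mean([r.val_report.r2 for r in results])),
                     "rmse": float(np.mean(val_rmses)),
                     "mbe": float(np.mean([r.val_report.mbe for r in results]))},
        "test": results[best].report,
        "best_fold": best,
        "fold_results": results,
    }


def ablate_wsd(world: World, widths=(16, 8, 8), seed: int = 0,
               train_overrides: dict | None = None
               ) -> tuple[MetricsReport, MetricsReport]:
    """Identical pipeline and seed with vs without the WSD data source.

    The ablated arm removes smoke density everywhere it enters — the
    feature roster *and* the AOD gap filler's predictor set — so no smoke
    information is laundered through imputed AOD. Scoring uses the full
    held-out portion (val + test): the >35 ug/m3 stratum of a 10% test
    sliver holds too few desk-scale samples. Returns (with_wsd,
    without_wsd) reports.
    """
    fusion_config = FusionConfig(mode="leave_target_out")
    locations = world.stations.copy()
    locations["loc_id"] = locations["station_id"]
    targets = station_targets(world)
    targets["region"] = quadrant_regions(
        targets["lon"].to_numpy(), targets["lat"].to_numpy(),
        lon_mid=float(np.median(world.lon)), lat_mid=float(np.median(world.lat)))
    reports = []
    for include_wsd in (True, False):
        table = build_feature_table(world, locations,
                                    fusion_config=fusion_config,
                                    include_wsd=include_wsd)
        r = run_experiment(world, widths, seed, include_wsd=include_wsd,
                           table=table, targets=targets,
                           train_overrides=train_overrides,
                           report_on="heldout")
        reports.append(r.report)
    return reports[0], reports[1]


def compare_baselines(world: World, widths=(16, 8, 8), seed: int = 0,
                      train_overrides: dict | None = None,
                      include_lstm: bool = True) -> dict:
    """Bi-LSTM vs unidirectional LSTM vs point-to-point random forest,
    all on identical sample-level splits."""
    table, targets = prepare_station_data(world)
    bi = run_experiment(world, widths, seed, table=table, targets=targets,
                        train_overrides=train_overrides)
    uni = None
    if include_lstm:
        uni = run_experiment(world, widths, seed, table=table, targets=targets,
                             model_overrides={"bidirectional": False,
                                              "width_interpretation": "per_direction"},
                             train_overrides=train_overrides)

    # random forest consumes only the day-t feature vector
    names = bi.pipeline.feature_names
    rows = table.reindex(pd.MultiIndex.from_arrays(
        [targets["loc_id"], pd.to_datetime(targets["date"])]))
    X_day = rows[names].to_numpy(dtype=float)
    y = targets["y"].to_numpy(dtype=float)
    tr, te = bi.splits["train"], bi.splits["test"]
    rf_pred = np.maximum(random_forest_baseline(
        X_day[tr], y[tr], X_day[te], seed=seed), 0.0)
    rf_pset = PredictionSet(y[te], rf_pred, targets.iloc[te])
    out = {"bilstm": bi, "rf": metrics_report(rf_pset),
           "rf_predictions": rf_pset, "splits": bi.splits}
    if uni is not None:
        out["lstm"] = uni
    return out
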