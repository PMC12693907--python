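"""End-to-end orchestration: environment forecast → color-fraction forecast
→ maturity grade and quality traits.

The environment stage forecasts hour by hour; the color stage works on the
daily grid (one fruit photo per day), consuming 24-day windows of
daily-mean environment plus the lagged surface fractions and predicting the
next day's fractions.  Integrated inference chains a recursive hourly
environment rollout (aggregated to daily means) into the daily color
recursion, grades maturity from the predicted red coverage, and maps the
predicted red fraction to the quality network's a_norm input through a
calibrated monotone (isotonic) proxy fitted on training plants — no future
image exists at prediction time, so the proxy stands in for the a* feature
the camera would measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from . import preprocess
from .color import grade_maturity
from .env_model import ARCHITECTURES, EnvLSTMForecaster, rollout
from .maturity_model import GRUAttentionForecaster
from .metrics import MetricReport
from .preprocess import ScalerParams, minmax_fit_transform, windowize
from .quality_model import QualityDNNRegressor
from .simulate import TRAITS, SimStudy, VARIABLES

__all__ = [
    "PipelineModels",
    "train_pipeline",
    "integrated_predict",
    "evaluate_integrated",
    "evaluate_env_models",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineModels:
    env_models: dict  # variable -> EnvLSTMForecaster
    maturity_model: GRUAttentionForecaster
    quality_model: QualityDNNRegressor
    env_scaler: ScalerParams
    red_to_a_norm: IsotonicRegression
    time_steps: int = 24
    seed: int = 0
    split: preprocess.SplitAssignment | None = None


def daily_env_means(env_values: np.ndarray) -> np.ndarray:
    """Collapse an hourly (n, 3) series to whole-day means."""
    env_values = np.asarray(env_values, dtype=float)
    days = len(env_values) // 24
    return env_values[: days * 24].reshape(days, 24, -1).mean(axis=1)


def _plant_daily_features(daily: pd.DataFrame, env_day_scaled: np.ndarray) -> np.ndarray:
    """(days, 6) rows of [scaled daily env ‖ fractions] for one plant."""
    env_rows = env_day_scaled[daily.day.to_numpy()]
    return np.column_stack([env_rows, daily[["red", "yellow", "green"]].to_numpy()])


def _maturity_windows(study: SimStudy, plants, env_day_scaled: np.ndarray, T: int):
    xs, ys = [], []
    for plant in plants:
        daily = study.daily[study.daily.plant_id == plant]
        feats = _plant_daily_features(daily, env_day_scaled)
        ds = windowize(feats, T)
        xs.append(ds.X)
        ys.append(ds.y[:, 3:])  # next-day fractions
    return np.concatenate(xs), np.concatenate(ys)


def train_pipeline(
    study: SimStudy,
    seed: int = 0,
    env_epochs: int = 150,
    maturity_epochs: int = 150,
    quality_epochs: int = 100,
    quality_lr_decay: float = 1.0,
    time_steps: int = 24,
    env_hidden: dict | None = None,
    maturity_hidden: int = 64,
    env_train_days: int | None = None,
) -> PipelineModels:
    """Fit the three stages on a simulated (or equivalently structured) study.

    Plants are split 7:2:1 with a temporal gap; the environment models train
    on the pre-boundary hourly series, the color model on training-plant
    24-day windows, the quality model on training-plant daily
    (a_norm, traits) pairs.  Per-stage optimizer settings keep their
    standard defaults; epoch counts are exposed so callers can scale runs.
    """
    split = preprocess.split_by_plant(
        study.records.plant_id.to_numpy(), study.records.timestamp.to_numpy(), seed=seed
    )
    train_plants = split.plants("train")

    # --- environment stage -------------------------------------------------
    env = study.env
    boundary_idx = int(np.searchsorted(env.timestamps, split.temporal_boundary))
    env_train_vals = env.values[:boundary_idx]
    if env_train_days is not None:
        env_train_vals = env_train_vals[: env_train_days * 24]
    env_scaled_train, scaler = minmax_fit_transform(env_train_vals, variables=list(VARIABLES))
    env_ds = windowize(env_scaled_train, time_steps)
    env_models = {}
    for j, var in enumerate(VARIABLES):
        hidden = (env_hidden or {}).get(var, ARCHITECTURES[var])
        model = EnvLSTMForecaster(
            variable=var, hidden_layers=hidden, time_steps=time_steps,
            epochs=env_epochs, seed=seed + j,
        )
        model.fit(env_ds.X, env_ds.y[:, j])
        env_models[var] = model
        logger.info("trained env model %s (%d epochs)", var, len(model.loss_history_))

    # --- maturity stage (daily grid) ---------------------------------------
    env_scaled_full, _ = minmax_fit_transform(env.values, scaler)
    env_day_scaled = daily_env_means(env_scaled_full)
    Xm, Ym = _maturity_windows(study, train_plants, env_day_scaled, time_steps)
    maturity = GRUAttentionForecaster(
        hidden_size=maturity_hidden, time_steps=time_steps, epochs=maturity_epochs, seed=seed
    )
    maturity.fit(Xm, Ym)
    logger.info("trained maturity model (%d epochs)", len(maturity.loss_history_))

    # --- quality stage ------------------------------------------------------
    daily_train = study.daily[study.daily.plant_id.isin(train_plants)]
    quality = QualityDNNRegressor(epochs=quality_epochs, lr_decay=quality_lr_decay, seed=seed)
    quality.fit(daily_train.a_norm.to_numpy(), daily_train[TRAITS].to_numpy())
    logger.info("trained quality model (%d epochs)", len(quality.loss_history_))

    proxy = IsotonicRegression(out_of_bounds="clip")
    proxy.fit(daily_train.red.to_numpy(), daily_train.a_norm.to_numpy())

    return PipelineModels(env_models, maturity, quality, scaler, proxy, time_steps, seed, split)


def forecast_env_daily(
    models: PipelineModels, env_seed_window: np.ndarray, horizon_days: int
) -> tuple[np.ndarray, np.ndarray]:
    """Recursive hourly environment rollout aggregated to daily means.

    Returns (hourly forecast in raw units, scaled daily means), both
    covering ``horizon_days`` days beyond the seed window.
    """
    scaled, _ = minmax_fit_transform(np.asarray(env_seed_window, dtype=float), models.env_scaler)
    hourly_scaled = rollout(models.env_models, scaled, horizon_days * 24)
    hourly = preprocess.inverse_transform(hourly_scaled, models.env_scaler)
    return hourly, daily_env_means(hourly_scaled)


def rollout_daily_fractions(
    models: PipelineModels, window: np.ndarray, env_day_scaled_future: np.ndarray, horizon_days: int
) -> np.ndarray:
    """Daily color-fraction recursion fed with forecast daily-mean environment."""
    if horizon_days < 1:
        raise ValueError("horizon must be >= 1 day")
    window = np.asarray(window, dtype=float).copy()
    out = np.empty((horizon_days, 3))
    for d in range(horizon_days):
        frac = models.maturity_model.predict(window)
        out[d] = frac
        next_row = np.concatenate([env_day_scaled_future[d], frac])
        window = np.vstack([window[1:], next_row])
    return out


def integrated_predict(
    models: PipelineModels,
    env_window: np.ndarray,
    color_history: np.ndarray,
    env_history: np.ndarray,
    horizon_days: int,
) -> pd.DataFrame:
    """Recursive integrated forecast, one row per forecast day.

    ``env_window``: (24, 3) raw-unit hourly environment seeding the hourly
    rollout; ``color_history``: (T, 3) daily fractions and ``env_history``:
    (T, 3) raw-unit daily-mean environment for the same T past days.
    Each day chains environment → fractions → maturity grade → a_norm proxy
    → quality traits.
    """
    if horizon_days < 1:
        raise ValueError("horizon must be >= 1 day")
    env_hourly, env_day_scaled = forecast_env_daily(models, env_window, horizon_days)
    hist_scaled, _ = minmax_fit_transform(np.asarray(env_history, dtype=float), models.env_scaler)
    window = np.column_stack([hist_scaled, np.asarray(color_history, dtype=float)])
    fractions = rollout_daily_fractions(models, window, env_day_scaled, horizon_days)
    a_norm = models.red_to_a_norm.predict(fractions[:, 0])
    traits = models.quality_model.predict(a_norm)
    env_day = daily_env_means(env_hourly)
    rows = {
        "day": np.arange(1, horizon_days + 1),
        **{v: env_day[:, j] for j, v in enumerate(VARIABLES)},
        "red": fractions[:, 0],
        "yellow": fractions[:, 1],
        "green": fractions[:, 2],
        "maturity_level": [grade_maturity(r, y) for r, y in fractions[:, :2]],
        "a_norm": a_norm,
    }
    for j, t in enumerate(TRAITS):
        rows[t] = traits[:, j]
    return pd.DataFrame(rows)


def evaluate_integrated(models: PipelineModels, study: SimStudy, plants=None) -> pd.DataFrame:
    """Whole-system evaluation on held-out plants.

    One hourly environment rollout (seeded with the first observed day)
    covers the full study period; each plant's first T monitored days seed
    the color window, and the daily recursion spans the rest of its
    monitoring.  Returns a long frame of (plant, day, trait, truth,
    prediction) rows to score per trait with :func:`tomaqual.metrics.r2`.
    """
    if plants is None:
        if models.split is None:
            raise ValueError("no split stored; pass plants explicitly")
        plants = models.split.plants("test")
    T = models.time_steps
    total_days = len(study.env.timestamps) // 24
    _, env_day_scaled_future = forecast_env_daily(models, study.env.values[:24], total_days - 1)
    # absolute-day table of predicted scaled daily means (day 0 = observed seed)
    env_scaled_obs, _ = minmax_fit_transform(study.env.values[:24], models.env_scaler)
    env_day_pred = np.vstack([env_scaled_obs.mean(axis=0), env_day_scaled_future])
    env_scaled_full, _ = minmax_fit_transform(study.env.values, models.env_scaler)
    env_day_obs = daily_env_means(env_scaled_full)
    rows = []
    for plant in plants:
        daily = study.daily[study.daily.plant_id == plant].reset_index(drop=True)
        if len(daily) <= T:
            continue
        hist = daily.iloc[:T]
        window = np.column_stack(
            [env_day_obs[hist.day.to_numpy()], hist[["red", "yellow", "green"]].to_numpy()]
        )
        horizon = len(daily) - T
        future_days = daily.day.to_numpy()[T:]
        fractions = rollout_daily_fractions(models, window, env_day_pred[future_days], horizon)
        a_norm = models.red_to_a_norm.predict(fractions[:, 0])
        traits = models.quality_model.predict(a_norm)
        for i in range(horizon):
            truth_row = daily.iloc[T + i]
            for j, t in enumerate(TRAITS):
                rows.append(
                    {
                        "plant_id": plant,
                        "day": int(truth_row.day),
                        "trait": t,
                        "truth": truth_row[t],
                        "prediction": traits[i, j],
                        "red_true": truth_row.red,
                        "red_pred": fractions[i, 0],
                    }
                )
    return pd.DataFrame(rows)


def evaluate_env_models(models: PipelineModels, env_values: np.ndarray) -> MetricReport:
    """Next-step metrics of the environment models on a raw-unit series."""
    scaled, _ = minmax_fit_transform(np.asarray(env_values, dtype=float), models.env_scaler)
    ds = windowize(scaled, models.time_steps)
    report = MetricReport("env_lstm", "test")
    for j, var in enumerate(VARIABLES):
        pred = models.env_models[var].predict(ds.X)
        report.add(var, ds.y[:, j], pred)
    return report
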