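"""Quality control, gap filling, scaling, windowing and plant-wise splitting.

The sensor pipeline mirrors common greenhouse-logger practice: box-plot
outlier screening, gap filling that distinguishes short gaps (linear
interpolation between the bracketing valid points) from long gaps (copy from
the nearest prior day with matching weather), min–max normalization to
[0, 1], a plant-disjoint 7:2:1 split with a temporal gap, and sliding-window
supervised dataset construction (S, T, X) with a next-step target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SensorSeries",
    "ScalerParams",
    "SplitAssignment",
    "WindowedDataset",
    "DegenerateInputError",
    "DegenerateScaleError",
    "UnfillableGapError",
    "EmptyDatasetError",
    "boxplot_bounds",
    "flag_outliers",
    "fill_gaps",
    "fit_scaler",
    "minmax_fit_transform",
    "inverse_transform",
    "split_by_plant",
    "windowize",
    "read_sensor_csv",
    "write_sensor_csv",
]


class DegenerateInputError(ValueError):
    pass


class DegenerateScaleError(ValueError):
    pass


class UnfillableGapError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


@dataclass
class SensorSeries:
    """Fixed-step multivariate sensor record with an explicit missing mask.

    ``values`` is (time × variable); ``missing_mask`` is True where the value
    is absent (the stored number there is undefined).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    variables: list[str]
    missing_mask: np.ndarray

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.variables):
            raise ValueError("values must be (time, variable) matching variable names")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps length must match values")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.view("int64"))
            if not (deltas > 0).all():
                raise ValueError("timestamps must be strictly increasing")
            if not (deltas == deltas[0]).all():
                raise ValueError("timestamps must have a constant step")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.isfinite(observed).all():
            raise ValueError("observed values must be finite")

    @property
    def step(self) -> pd.Timedelta:
        return self.timestamps[1] - self.timestamps[0]

    def copy(self) -> "SensorSeries":
        return SensorSeries(
            self.timestamps.copy(), self.values.copy(), list(self.variables), self.missing_mask.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.timestamps, columns=self.variables)
        return frame.mask(pd.DataFrame(self.missing_mask, index=self.timestamps, columns=self.variables))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SensorSeries":
        values = frame.to_numpy(dtype=float)
        mask = ~np.isfinite(values)
        values = np.where(mask, 0.0, values)
        return cls(pd.DatetimeIndex(frame.index), values, list(frame.columns), mask)


def read_sensor_csv(path) -> SensorSeries:
    """Read a sensor CSV: ISO-8601 ``timestamp`` column + one column per variable.

    Empty cells are missing values.
    """
    frame = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
    return SensorSeries.from_frame(frame)


def write_sensor_csv(series: SensorSeries, path) -> None:
    frame = series.to_frame()
    frame.index.name = "timestamp"
    frame.to_csv(path)


# -- QC --------------------------------------------------------------------


def boxplot_bounds(values) -> tuple[float, float]:
    """Tukey box-plot fences: (Q1 − 1.5·IQR, Q3 + 1.5·IQR).

    Quartiles use the sorted-order linear-interpolation convention.
    Requires at least 4 finite values.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 4:
        raise DegenerateInputError("boxplot_bounds needs at least 4 finite values")
    q1, q3 = np.percentile(finite, [25, 75], method="linear")
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def flag_outliers(series: SensorSeries) -> tuple[SensorSeries, dict]:
    """Mark box-plot outliers (per variable, full series) as missing."""
    out = series.copy()
    report = {}
    for j, name in enumerate(series.variables):
        col = series.values[:, j]
        observed = ~series.missing_mask[:, j]
        lower, upper = boxplot_bounds(col[observed])
        bad = observed & ((col < lower) | (col > upper))
        out.missing_mask[:, j] |= bad
        report[name] = {"lower": lower, "upper": upper, "flagged": int(bad.sum())}
    return out, report


# -- gap filling -----------------------------------------------------------


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Consecutive-missing runs as [start, stop) index pairs."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _match_historical_day(day: pd.Timestamp, col: pd.Series, sigma: float) -> pd.Timestamp | None:
    """Nearest prior day whose daily mean differs by < sigma; ties to most recent.

    Falls back to the most recent complete prior day when the gap day has no
    observed points of its own to compare against.
    """
    daily = col.resample("D").mean()
    candidates = daily[(daily.index < day.normalize()) & daily.notna()]
    if candidates.empty:
        return None
    target = daily.get(day.normalize(), np.nan)
    if np.isfinite(target) and sigma > 0:
        close = candidates[(candidates - target).abs() < sigma]
        if not close.empty:
            return close.index[-1]
        return (candidates - target).abs().idxmin()
    return candidates.index[-1]


def fill_gaps(
    series: SensorSeries,
    history: SensorSeries | None = None,
    max_linear_gap: int = 5,
) -> tuple[SensorSeries, dict]:
    """Fill all missing runs; returns the completed series and a QC report.

    Runs of ≤ ``max_linear_gap`` consecutive missing points are filled by
    linear interpolation between the bracketing valid points
    y_a + (y_b − y_a)·(t − t_a)/(t_b − t_a).  Longer runs (and edge runs with
    no bracketing point) are copied, time-of-day aligned, from the nearest
    prior day of ``history`` (default: the series itself) whose daily mean of
    the same variable lies within one standard deviation of daily means.
    """
    out = series.copy()
    hist_frame = (history or series).to_frame()
    counts = {"linear": 0, "historical": 0}
    for j, name in enumerate(series.variables):
        mask = series.missing_mask[:, j]
        if not mask.any():
            continue
        col_hist = hist_frame[name] if name in hist_frame else hist_frame.iloc[:, j]
        daily = col_hist.resample("D").mean().dropna()
        sigma = float(daily.std(ddof=1)) if len(daily) > 1 else 0.0
        for start, stop in _missing_runs(mask):
            length = stop - start
            bracketed = start > 0 and stop < len(mask)
            if length <= max_linear_gap and bracketed:
                t_a, y_a = start - 1, out.values[start - 1, j]
                t_b, y_b = stop, out.values[stop, j]
                for t in range(start, stop):
                    out.values[t, j] = y_a + (y_b - y_a) * (t - t_a) / (t_b - t_a)
                counts["linear"] += length
            else:
                day = series.timestamps[start]
                match = _match_historical_day(day, col_hist, sigma)
                if match is None:
                    raise UnfillableGapError(
                        f"no bracketing points and no prior-day match for '{name}' at {day}"
                    )
                for t in range(start, stop):
                    ts = series.timestamps[t]
                    src = match + (ts - ts.normalize())
                    val = col_hist.get(src, np.nan)
                    if not np.isfinite(val):
                        val = col_hist.loc[:src].dropna().iloc[-1]
                    out.values[t, j] = val
                counts["historical"] += length
            out.missing_mask[start:stop, j] = False
    return out, counts


# -- scaling ---------------------------------------------------------------


@dataclass
class ScalerParams:
    """Per-variable min/max fitted on the training split."""

    data_min: np.ndarray
    data_max: np.ndarray
    variables: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data_min = np.asarray(self.data_min, dtype=float)
        self.data_max = np.asarray(self.data_max, dtype=float)
        if (self.data_max < self.data_min).any():
            raise ValueError("data_max must be >= data_min")


def fit_scaler(values: np.ndarray, variables: list[str] | None = None) -> ScalerParams:
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(axis=0), values.max(axis=0)
    if np.any(hi == lo):
        raise DegenerateScaleError("constant variable: d_max equals d_min")
    return ScalerParams(lo, hi, variables or [])


def minmax_fit_transform(
    values: np.ndarray, scaler: ScalerParams | None = None, variables: list[str] | None = None
) -> tuple[np.ndarray, ScalerParams]:
    """y = (d − d_min)/(d_max − d_min); no clipping of out-of-range values."""
    values = np.asarray(values, dtype=float)
    if scaler is None:
        scaler = fit_scaler(values, variables)
    return (values - scaler.data_min) / (scaler.data_max - scaler.data_min), scaler


def inverse_transform(scaled: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * (scaler.data_max - scaler.data_min) + scaler.data_min


# -- splitting -------------------------------------------------------------


@dataclass
class SplitAssignment:
    assignment: dict  # plant_id -> "train" | "validation" | "test"
    ratios: tuple
    temporal_boundary: pd.Timestamp
    dropped_records: np.ndarray  # record indices excluded to enforce the gap
    seed: int

    def plants(self, split: str) -> list:
        return sorted([p for p, s in self.assignment.items() if s == split], key=str)


def split_by_plant(
    plant_ids,
    record_times,
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Plant-disjoint train/validation/test split with a temporal gap.

    Plants are ordered by their first record; the latest ``ratios[2]`` share
    becomes the test set, so every test record postdates the boundary (the
    earliest test-plant record).  Train/validation plants are shuffled with
    the seeded RNG; their records at or after the boundary are reported in
    ``dropped_records`` so callers can exclude them.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    plant_ids = np.asarray(plant_ids)
    record_times = pd.DatetimeIndex(record_times)
    if len(plant_ids) != len(record_times):
        raise ValueError("plant_ids and record_times must align")
    first_time = pd.Series(record_times, index=None).groupby(plant_ids).min()
    plants = list(first_time.sort_values(kind="stable").index)
    n = len(plants)
    if n < 10:
        raise ValueError("need at least 10 plants to split")
    n_test = max(1, round(ratios[2] * n))
    n_train = round(ratios[0] * n)
    n_train = min(n_train, n - n_test - 1)
    test_plants = plants[-n_test:]
    rest = plants[:-n_test]
    rng = np.random.default_rng(seed)
    rest = [rest[i] for i in rng.permutation(len(rest))]
    train_plants, val_plants = rest[:n_train], rest[n_train:]
    assignment = {p: "train" for p in train_plants}
    assignment.update({p: "validation" for p in val_plants})
    assignment.update({p: "test" for p in test_plants})
    boundary = record_times[np.isin(plant_ids, test_plants)].min()
    non_test = ~np.isin(plant_ids, test_plants)
    dropped = np.flatnonzero(non_test & (record_times >= boundary))
    return SplitAssignment(assignment, tuple(ratios), boundary, dropped, seed)


# -- windowing -------------------------------------------------------------


@dataclass
class WindowedDataset:
    """Sliding windows (S, T, X) with aligned next-step targets (S, X)."""

    X: np.ndarray
    y: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def windowize(values: np.ndarray, T: int, X: int | None = None) -> WindowedDataset:
    """Stride-1 sliding windows with a horizon-1 target; S = length − T."""
    if isinstance(values, SensorSeries):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if X is not None and values.shape[1] != X:
        raise ValueError(f"expected {X} features, got {values.shape[1]}")
    length = len(values)
    if length < T + 1:
        raise EmptyDatasetError(f"series of length {length} yields no window/target pairs for T={T}")
    windows = np.lib.stride_tricks.sliding_window_view(values, (T, values.shape[1]))[:-1, 0]
    return WindowedDataset(windows.copy(), values[T:].copy())


def write_qc_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
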