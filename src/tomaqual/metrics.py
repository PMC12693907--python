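"""Evaluation metrics (R², MAE, RMSE) and tabular/JSON reporting."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["r2", "mae", "rmse", "MetricReport", "summary_table", "stage_percentages"]


def _pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return y_true, y_pred


def r2(y_true, y_pred) -> float:
    """Coefficient of determination 1 − Σ(ŷ−y)² / Σ(y−ȳ)²."""
    y_true, y_pred = _pair(y_true, y_pred)
    if y_true.size < 2:
        raise ValueError("R² needs at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: y_true has zero variance")
    return 1.0 - float(np.sum((y_pred - y_true) ** 2)) / ss_tot


def mae(y_true, y_pred) -> float:
    y_true, y_pred = _pair(y_true, y_pred)
    if y_true.size == 0:
        raise ValueError("MAE needs at least 1 sample")
    return float(np.mean(np.abs(y_pred - y_true)))


def rmse(y_true, y_pred) -> float:
    y_true, y_pred = _pair(y_true, y_pred)
    if y_true.size == 0:
        raise ValueError("RMSE needs at least 1 sample")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


@dataclass
class MetricReport:
    """Per-target R²/MAE/RMSE for one model on one evaluation split."""

    model: str
    split: str
    metrics: dict = field(default_factory=dict)  # target -> {"r2","mae","rmse","n"}

    def add(self, target: str, y_true, y_pred) -> None:
        y_true, y_pred = _pair(y_true, y_pred)
        self.metrics[target] = {
            "r2": r2(y_true, y_pred),
            "mae": mae(y_true, y_pred),
            "rmse": rmse(y_true, y_pred),
            "n": int(y_true.size),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"model": self.model, "split": self.split, "metrics": self.metrics}, fh, indent=2)


def summary_table(reports: list[MetricReport]) -> pd.DataFrame:
    """Long-form model × target × metric table."""
    rows = []
    for rep in reports:
        for target, vals in rep.metrics.items():
            rows.append(
                {
                    "model": rep.model,
                    "target": target,
                    "r2": vals["r2"],
                    "mae": vals["mae"],
                    "rmse": vals["rmse"],
                    "n": vals["n"],
                }
            )
    return pd.DataFrame(rows)


def stage_percentages(counts) -> tuple[np.ndarray, int]:
    """Percentage share of each maturity stage from per-stage image counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return 100.0 * counts / total, int(total)
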