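"""Paired-series model evaluation: R², index of agreement, daily averaging.

Conventions (the common defaults in air-quality model evaluation):

* R² is the squared Pearson correlation of predicted vs observed — not a
  regression-through-origin R² — and is therefore invariant to affine
  rescaling of either series.
* The index of agreement is Willmott's (1981) original squared-deviation
  form,

      d = 1 - Σ(Pᵢ - Oᵢ)² / Σ(|Pᵢ - Ō| + |Oᵢ - Ō|)²,

  bounded in [0, 1] with d = 1 iff prediction equals observation.  Unlike
  R² it penalizes bias, and it is *not* invariant to affine transforms.
* Hourly series are averaged to calendar days only when at least 75% of
  the hours are valid (configurable); incomplete days propagate as
  missing.

Undefined statistics (constant series for R², zero denominator for IOA
with imperfect agreement) are returned as NaN rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from firehia.errors import InvalidParameterError
from firehia.grid import ConcentrationGrid

DAILY_COMPLETENESS = 0.75


@dataclass
class StationSeries:
    """Paired predicted/observed series at one monitoring station."""

    station_id: str
    x: float
    y: float
    timestamps: pd.DatetimeIndex
    observed: np.ndarray
    predicted: np.ndarray
    valid: Optional[np.ndarray] = None
    variable: str = "pm25"

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.observed) & np.isfinite(self.predicted)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.timestamps)
        if not (len(self.observed) == len(self.predicted) == len(self.valid) == n):
            raise InvalidParameterError("paired arrays must share the timestamp length")
        if n > 1 and not self.timestamps.is_monotonic_increasing:
            raise InvalidParameterError("timestamps must be monotone increasing")

    def pairs(self) -> Tuple[np.ndarray, np.ndarray]:
        """Valid (predicted, observed) pairs."""
        return self.predicted[self.valid], self.observed[self.valid]


def index_of_agreement(pred, obs) -> float:
    """Willmott's index of agreement (squared form), in [0, 1].

    Returns 1.0 for exact agreement even when both series are constant;
    returns NaN when the denominator vanishes with imperfect agreement.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise InvalidParameterError("need two equal-length series with n >= 2")
    num = float(np.sum((pred - obs) ** 2))
    if num == 0.0:
        return 1.0
    obar = obs.mean()
    den = float(np.sum((np.abs(pred - obar) + np.abs(obs - obar)) ** 2))
    if den == 0.0:
        return float("nan")
    return 1.0 - num / den


def r_squared(pred, obs) -> float:
    """Squared Pearson correlation; NaN when either series is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise InvalidParameterError("need two equal-length series with n >= 2")
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        return float("nan")
    p, o = pred - pred.mean(), obs - obs.mean()
    r = float(np.dot(p, o) / np.sqrt(np.dot(p, p) * np.dot(o, o)))
    return r * r


def daily_average(
    series: StationSeries, completeness: float = DAILY_COMPLETENESS
) -> StationSeries:
    """Collapse an hourly station series to calendar-day means.

    A day's mean is computed from its valid hours when the valid fraction
    is at least *completeness* (default 0.75); otherwise the day is
    missing.  The day fraction uses the day's total hours present in the
    series, so partially recorded days at the episode edges are judged
    against what was recorded.
    """
    df = pd.DataFrame(
        {
            "day": series.timestamps.floor("D"),
            "obs": np.where(series.valid, series.observed, np.nan),
            "pred": np.where(series.valid, series.predicted, np.nan),
            "valid": series.valid.astype(float),
        }
    )
    g = df.groupby("day")
    frac = g["valid"].mean()
    obs = g["obs"].mean()
    pred = g["pred"].mean()
    keep = frac >= completeness
    obs[~keep] = np.nan
    pred[~keep] = np.nan
    return StationSeries(
        station_id=series.station_id,
        x=series.x,
        y=series.y,
        timestamps=pd.DatetimeIndex(obs.index),
        observed=obs.to_numpy(),
        predicted=pred.to_numpy(),
        variable=series.variable,
    )


def extract_prediction_at_station(
    grid: ConcentrationGrid, location: Tuple[float, float]
) -> np.ndarray:
    """Grid value of the cell containing *location*, per time step.

    Nearest-cell (containing-cell) convention, no interpolation; a point
    on a cell edge deterministically belongs to the lower-index cell.
    Raises if the location is outside the grid extent.
    """
    i, j = grid.cell_index(*location)
    return grid.values[:, i, j].copy()


def evaluate_station(series: StationSeries, scale: str = "hourly") -> dict:
    """Summary statistics for one station: n, R², IOA, RMSE, mean bias."""
    pred, obs = series.pairs()
    n = int(pred.size)
    if n >= 2:
        r2, ioa = r_squared(pred, obs), index_of_agreement(pred, obs)
        rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
        bias = float(np.mean(pred - obs))
    else:
        r2 = ioa = rmse = bias = float("nan")
    return {
        "station_id": series.station_id,
        "variable": series.variable,
        "scale": scale,
        "n": n,
        "r2": r2,
        "ioa": ioa,
        "rmse": rmse,
        "mean_bias": bias,
    }
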