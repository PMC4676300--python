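"""Forecast-proficiency curves from paired true and forecast trajectories.

Forecast proficiency is any measure of how useful a forecast is — a
correlation, an error statistic, variance explained — evaluated as a
function of forecast distance (lead time here; km or MYA elsewhere in the
package). Curves produced here feed the horizon estimators in
:mod:`ecohorizon.horizon`.

Windows slide over forecast lead time and each window is labelled by its
centre, so a proficiency value describes forecast quality *around* that
lead time. Windows whose truth or forecast has zero variance yield a
missing value (NaN) which is propagated, never imputed: silently recording
0 would bias every downstream horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "ForecastEnsemble",
    "ProficiencyCurve",
    "windowed_correlation_curve",
    "error_metric_curve",
    "r_squared_curve",
    "aggregate_curves",
]

_TIME_UNITS = {"generation", "day", "arbitrary"}
_DISTANCE_UNITS = {"generation", "day", "km", "MYA", "arbitrary"}

#: metrics where larger values mean better forecasts
_HIGHER_BETTER = {"correlation", "r_squared", "auc", "sorensen", "sqrt_pearson"}
_ERROR_METRICS = ("bias", "MSE", "RMSE", "MAE")


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered series of one state variable (abundance or biomass)."""

    times: np.ndarray
    values: np.ndarray
    unit: str = "generation"
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValueError("times and values must have equal length")
        if len(times) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.unit not in _TIME_UNITS:
            raise ValueError(f"unknown time unit {self.unit!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ForecastEnsemble:
    """A truth trajectory plus one or more forecast replicates on the same time axis."""

    truth: Trajectory
    forecasts: tuple[Trajectory, ...]

    def __post_init__(self) -> None:
        forecasts = tuple(self.forecasts)
        object.__setattr__(self, "forecasts", forecasts)
        if len(forecasts) < 1:
            raise ValueError("an ensemble needs at least one forecast")
        for f in forecasts:
            if not np.array_equal(f.times, self.truth.times):
                raise ValueError(
                    "every forecast must share the truth's time axis exactly"
                )

    @property
    def n_forecasts(self) -> int:
        return len(self.forecasts)


@dataclass
class ProficiencyCurve:
    """Proficiency as a function of forecast distance.

    ``replicate_proficiency`` when present is a (replicates x distances)
    matrix whose NaN-aware per-distance mean equals ``mean_proficiency``.
    ``band`` holds optional (lower, upper) percentile envelopes.
    """

    distances: np.ndarray
    mean_proficiency: np.ndarray
    metric_name: str
    higher_is_better: bool
    unit: str = "generation"
    replicate_proficiency: np.ndarray | None = None
    band: tuple[np.ndarray, np.ndarray] | None = None
    band_percentiles: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.mean_proficiency = np.asarray(self.mean_proficiency, dtype=float)
        if self.distances.ndim != 1:
            raise ValueError("distances must be one-dimensional")
        if self.distances.shape != self.mean_proficiency.shape:
            raise ValueError("distances and mean_proficiency must align")
        if not np.all(np.diff(self.distances) > 0):
            raise ValueError("distances must be strictly increasing")
        if self.unit not in _DISTANCE_UNITS:
            raise ValueError(f"unknown distance unit {self.unit!r}")
        if self.metric_name == "correlation":
            finite = self.mean_proficiency[np.isfinite(self.mean_proficiency)]
            if np.any(np.abs(finite) > 1 + 1e-9):
                raise ValueError("correlation proficiency must lie in [-1, 1]")
        if self.metric_name in {"r_squared", "auc", "sorensen"}:
            finite = self.mean_proficiency[np.isfinite(self.mean_proficiency)]
            if np.any((finite < -1e-9) | (finite > 1 + 1e-9)):
                raise ValueError(f"{self.metric_name} proficiency must lie in [0, 1]")
        if self.replicate_proficiency is not None:
            rep = np.asarray(self.replicate_proficiency, dtype=float)
            if rep.ndim != 2 or rep.shape[1] != len(self.distances):
                raise ValueError("replicate_proficiency must be replicates x distances")
            self.replicate_proficiency = rep
            rep_mean = nanmean_columns(rep)
            ok = np.isnan(rep_mean) == np.isnan(self.mean_proficiency)
            if not np.all(ok):
                raise ValueError("mean/replicate missingness disagree")
            both = ~np.isnan(rep_mean)
            if not np.allclose(
                rep_mean[both], self.mean_proficiency[both], atol=1e-8
            ):
                raise ValueError(
                    "mean_proficiency must equal the per-distance replicate mean"
                )

    def __len__(self) -> int:
        return len(self.distances)


def nanmean_columns(rep: np.ndarray) -> np.ndarray:
    """Per-column NaN-aware mean; all-NaN columns give NaN without warnings."""
    mask = ~np.isnan(rep)
    counts = mask.sum(axis=0)
    sums = np.where(mask, rep, 0.0).sum(axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _window_starts(n: int, window_length: int, step: int) -> np.ndarray:
    if window_length < 3:
        raise ValueError("window_length must be >= 3")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_length > n:
        raise ValueError("window_length exceeds trajectory length")
    return np.arange(0, n - window_length + 1, step)


def _window_centres(times: np.ndarray, starts: np.ndarray, window_length: int) -> np.ndarray:
    # label each window by the centre of its time span
    return np.array(
        [0.5 * (times[s] + times[s + window_length - 1]) for s in starts]
    )


def _windowed_pearson(truth: np.ndarray, fc: np.ndarray, starts: np.ndarray, w: int) -> np.ndarray:
    out = np.empty(len(starts))
    for k, s in enumerate(starts):
        x = truth[s : s + w]
        y = fc[s : s + w]
        sx = x - x.mean()
        sy = y - y.mean()
        vx = float(sx @ sx)
        vy = float(sy @ sy)
        if vx == 0.0 or vy == 0.0:
            out[k] = np.nan
            continue
        out[k] = float(sx @ sy) / np.sqrt(vx * vy)
    return np.clip(out, -1.0, 1.0)


def windowed_correlation_curve(
    ensemble: ForecastEnsemble, window_length: int = 10, step: int = 1
) -> ProficiencyCurve:
    """Moving-window Pearson correlation between truth and each forecast.

    One proficiency value per window position per forecast replicate; the
    curve's distance axis is the window-centre lead time and the mean curve
    is the NaN-aware mean across replicates.
    """
    t = ensemble.truth
    starts = _window_starts(len(t), window_length, step)
    centres = _window_centres(t.times, starts, window_length)
    rep = np.vstack(
        [
            _windowed_pearson(t.values, f.values, starts, window_length)
            for f in ensemble.forecasts
        ]
    )
    mean = nanmean_columns(rep)
    return ProficiencyCurve(
        distances=centres,
        mean_proficiency=mean,
        metric_name="correlation",
        higher_is_better=True,
        unit=t.unit,
        replicate_proficiency=rep,
    )


def error_metric_curve(
    ensemble: ForecastEnsemble,
    metric: str = "RMSE",
    window_length: int = 10,
    step: int = 1,
) -> ProficiencyCurve:
    """Windowed error statistics on residuals (predicted minus observed).

    ``metric`` is one of ``bias`` (mean error), ``MSE``, ``RMSE`` or ``MAE``;
    all are lower-is-better, and RMSE is sqrt(MSE) pointwise by construction.
    """
    if metric not in _ERROR_METRICS:
        raise ValueError(f"metric must be one of {_ERROR_METRICS}")
    t = ensemble.truth
    starts = _window_starts(len(t), window_length, step)
    centres = _window_centres(t.times, starts, window_length)
    rep = np.empty((ensemble.n_forecasts, len(starts)))
    for i, f in enumerate(ensemble.forecasts):
        resid = f.values - t.values
        for k, s in enumerate(starts):
            e = resid[s : s + window_length]
            if metric == "bias":
                rep[i, k] = e.mean()
            elif metric == "MSE":
                rep[i, k] = np.mean(e**2)
            elif metric == "RMSE":
                rep[i, k] = np.sqrt(np.mean(e**2))
            else:  # MAE
                rep[i, k] = np.mean(np.abs(e))
    return ProficiencyCurve(
        distances=centres,
        mean_proficiency=rep.mean(axis=0),
        metric_name=metric,
        higher_is_better=False,
        unit=t.unit,
        replicate_proficiency=rep,
    )


def r_squared_curve(
    ensemble: ForecastEnsemble,
    window_length: int = 10,
    step: int = 1,
    convention: str = "squared_correlation",
) -> ProficiencyCurve:
    """Windowed R-squared between observed and predicted values.

    The default convention is the squared Pearson correlation of observed vs
    predicted within each window, which is invariant to linear rescaling of
    the forecast. ``convention="one_minus_ss"`` instead uses
    1 - SSres/SStot (floored at 0), which additionally penalises bias.
    """
    if convention not in {"squared_correlation", "one_minus_ss"}:
        raise ValueError("unknown R-squared convention")
    t = ensemble.truth
    starts = _window_starts(len(t), window_length, step)
    centres = _window_centres(t.times, starts, window_length)
    rep = np.empty((ensemble.n_forecasts, len(starts)))
    for i, f in enumerate(ensemble.forecasts):
        if convention == "squared_correlation":
            rep[i] = _windowed_pearson(t.values, f.values, starts, window_length) ** 2
        else:
            for k, s in enumerate(starts):
                obs = t.values[s : s + window_length]
                pred = f.values[s : s + window_length]
                sstot = float(np.sum((obs - obs.mean()) ** 2))
                if sstot == 0.0:
                    rep[i, k] = np.nan
                    continue
                ssres = float(np.sum((obs - pred) ** 2))
                rep[i, k] = max(0.0, 1.0 - ssres / sstot)
    mean = nanmean_columns(rep)
    return ProficiencyCurve(
        distances=centres,
        mean_proficiency=mean,
        metric_name="r_squared",
        higher_is_better=True,
        unit=t.unit,
        replicate_proficiency=rep,
    )


def aggregate_curves(
    curves: Sequence[ProficiencyCurve],
    band: tuple[float, float] = (25.0, 75.0),
) -> ProficiencyCurve:
    """Pool replicate curves: per-distance mean plus percentile envelopes.

    All curves must share distances, metric and orientation. Each input
    curve's mean series becomes one replicate row of the output; percentile
    envelopes use linear interpolation between order statistics.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    ref = curves[0]
    for c in curves[1:]:
        if not np.array_equal(c.distances, ref.distances):
            raise ValueError("curves must share the same distance axis")
        if c.metric_name != ref.metric_name or c.higher_is_better != ref.higher_is_better:
            raise ValueError("curves must share metric and orientation")
    lo_p, hi_p = band
    if not (0 <= lo_p <= hi_p <= 100):
        raise ValueError("band percentiles must satisfy 0 <= lower <= upper <= 100")
    rep = np.vstack([c.mean_proficiency for c in curves])
    mean = nanmean_columns(rep)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(rep, lo_p, axis=0)
        hi = np.nanpercentile(rep, hi_p, axis=0)
    return ProficiencyCurve(
        distances=ref.distances.copy(),
        mean_proficiency=mean,
        metric_name=ref.metric_name,
        higher_is_better=ref.higher_is_better,
        unit=ref.unit,
        replicate_proficiency=rep,
        band=(lo, hi),
        band_percentiles=(lo_p, hi_p),
    )
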