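"""Forecast horizons: where proficiency crosses the usefulness threshold.

The forecast horizon is the first distance (lead time, km, MYA) at which
the proficiency curve crosses a stated threshold in a stated direction:

* ``falls_below`` — the usual temporal case: the curve starts useful and
  the horizon is where mean proficiency first drops below the threshold.
* ``rises_above`` — the phylogenetic case: proficiency improves with
  distance and the horizon is where the curve first becomes useful.

A curve that never crosses yields an infinite horizon (a fully
deterministic, perfectly specified model never degrades); a curve that
starts on the crossing's target side yields horizon 0. With replicate
curves the horizon is a distribution; infinities are ranked above all
finite values so that medians and percentile bands stay well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.interpolate import PchipInterpolator

from .proficiency import ProficiencyCurve

__all__ = [
    "HorizonEstimate",
    "HorizonDistribution",
    "horizon_from_curve",
    "horizon_distribution",
    "fit_decay_curve_horizon",
    "detect_blind_spots",
    "good_intervals",
]

_CROSSINGS = {"falls_below", "rises_above"}


@dataclass(frozen=True)
class HorizonEstimate:
    """A single threshold-crossing distance, possibly infinite."""

    horizon: float
    threshold: float
    crossing: str
    unit: str = "generation"
    interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.crossing not in _CROSSINGS:
            raise ValueError(f"crossing must be one of {sorted(_CROSSINGS)}")
        if not (self.horizon >= 0 or math.isinf(self.horizon)):
            raise ValueError("horizon must be >= 0 or +infinity")
        if self.interval is not None:
            lo, hi = self.interval
            if not (lo <= self.horizon <= hi):
                raise ValueError("interval must bracket the horizon")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.horizon)


@dataclass(frozen=True)
class HorizonDistribution:
    """Per-replicate horizons summarised by median and a percentile band.

    Infinite horizons are ranked above every finite value; the median is
    +infinity when more than half the replicates never cross. The mean is
    reported over finite values only, with the infinite count alongside.
    """

    horizons: np.ndarray
    threshold: float
    crossing: str
    unit: str = "generation"
    band_percentiles: tuple[float, float] = (25.0, 75.0)

    def __post_init__(self) -> None:
        h = np.asarray(self.horizons, dtype=float)
        object.__setattr__(self, "horizons", h)
        if h.ndim != 1 or len(h) < 1:
            raise ValueError("need at least one replicate horizon")
        if np.any(h < 0):
            raise ValueError("horizons must be non-negative")

    @property
    def n_infinite(self) -> int:
        return int(np.sum(np.isinf(self.horizons)))

    @property
    def median(self) -> float:
        return _percentile_with_inf(self.horizons, 50.0)

    @property
    def finite_mean(self) -> float:
        finite = self.horizons[np.isfinite(self.horizons)]
        return float(finite.mean()) if len(finite) else math.inf

    @property
    def band(self) -> tuple[float, float]:
        lo_p, hi_p = self.band_percentiles
        lo = _percentile_with_inf(self.horizons, lo_p)
        hi = _percentile_with_inf(self.horizons, hi_p)
        return lo, hi


def _percentile_with_inf(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile with infinities ranked above all
    finite values (interpolating into an infinite order statistic gives
    infinity, where numpy would produce NaN from inf - inf)."""
    arr = np.sort(np.asarray(values, dtype=float))
    pos = (len(arr) - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    if frac == 0.0 or arr[lo] == arr[hi]:
        return float(arr[lo])
    if math.isinf(arr[hi]):
        return math.inf
    return float(arr[lo] + frac * (arr[hi] - arr[lo]))


def _clean_curve(curve: ProficiencyCurve) -> tuple[np.ndarray, np.ndarray]:
    keep = ~np.isnan(curve.mean_proficiency)
    d = curve.distances[keep]
    p = curve.mean_proficiency[keep]
    if len(d) < 2:
        raise ValueError("curve has fewer than 2 non-missing points")
    return d, p


def _first_crossing(
    d: np.ndarray, p: np.ndarray, threshold: float, crossing: str, interpolation: str
) -> float:
    """First distance where p enters the crossing's target side of threshold."""
    if crossing == "falls_below":
        on_target = p < threshold
    else:
        on_target = p > threshold
    if on_target[0]:
        return 0.0
    idx = np.nonzero(on_target)[0]
    if len(idx) == 0:
        return math.inf
    j = int(idx[0])
    if interpolation == "step":
        return float(d[j])
    d0, d1 = d[j - 1], d[j]
    p0, p1 = p[j - 1], p[j]
    if p1 == p0:  # flat segment cannot cross; target reached at d1
        return float(d1)
    return float(d0 + (threshold - p0) * (d1 - d0) / (p1 - p0))


def horizon_from_curve(
    curve: ProficiencyCurve,
    threshold: float,
    crossing: str = "falls_below",
    interpolation: str = "linear",
) -> HorizonEstimate:
    """First threshold crossing of the curve's mean proficiency.

    Missing (NaN) points are skipped, never interpolated across as values;
    the crossing is linearly interpolated between the adjacent non-missing
    points (``interpolation="step"`` returns the first sampled distance on
    the target side instead).
    """
    if crossing not in _CROSSINGS:
        raise ValueError(f"crossing must be one of {sorted(_CROSSINGS)}")
    if interpolation not in {"linear", "step"}:
        raise ValueError("interpolation must be 'linear' or 'step'")
    _check_threshold(curve, threshold)
    d, p = _clean_curve(curve)
    h = _first_crossing(d, p, threshold, crossing, interpolation)
    return HorizonEstimate(horizon=h, threshold=threshold, crossing=crossing, unit=curve.unit)


def _check_threshold(curve: ProficiencyCurve, threshold: float) -> None:
    ranges = {
        "correlation": (-1.0, 1.0),
        "r_squared": (0.0, 1.0),
        "auc": (0.0, 1.0),
        "sorensen": (0.0, 1.0),
        "sqrt_pearson": (-1.0, 1.0),
    }
    if curve.metric_name in ranges:
        lo, hi = ranges[curve.metric_name]
        if not (lo <= threshold <= hi):
            raise ValueError(
                f"threshold {threshold} outside the range of metric {curve.metric_name!r}"
            )


def horizon_distribution(
    curves: Sequence[ProficiencyCurve] | ProficiencyCurve,
    threshold: float,
    crossing: str = "falls_below",
    band: tuple[float, float] = (25.0, 75.0),
    interpolation: str = "linear",
    on_missing: str = "error",
) -> HorizonDistribution:
    """Horizon computed per replicate curve, then summarised.

    Accepts either a list of curves or a single curve carrying a replicate
    matrix (each row treated as one replicate curve). ``on_missing``
    governs replicate curves with fewer than 2 defined points (e.g. a
    zero-variance observable): ``"error"`` raises, ``"zero"`` records a
    horizon of 0 (no distance at which the forecast is demonstrably
    useful), ``"skip"`` drops the replicate.
    """
    if on_missing not in {"error", "zero", "skip"}:
        raise ValueError("on_missing must be 'error', 'zero' or 'skip'")
    if isinstance(curves, ProficiencyCurve):
        if curves.replicate_proficiency is None:
            raise ValueError("single curve must carry replicate_proficiency")
        base = curves
        rows = curves.replicate_proficiency
        per_rep = []
        _check_threshold(base, threshold)
        for row in rows:
            keep = ~np.isnan(row)
            if keep.sum() < 2:
                if on_missing == "error":
                    raise ValueError("replicate curve has fewer than 2 non-missing points")
                if on_missing == "zero":
                    per_rep.append(0.0)
                continue
            per_rep.append(
                _first_crossing(
                    base.distances[keep], row[keep], threshold, crossing, interpolation
                )
            )
        unit = base.unit
    else:
        if len(curves) < 2:
            raise ValueError("need at least 2 replicate curves")
        per_rep = [
            horizon_from_curve(c, threshold, crossing, interpolation).horizon
            for c in curves
        ]
        unit = curves[0].unit
    return HorizonDistribution(
        horizons=np.asarray(per_rep, dtype=float),
        threshold=threshold,
        crossing=crossing,
        unit=unit,
        band_percentiles=band,
    )


# ---------------------------------------------------------------------------
# fitted-curve horizons

def _exp_model(d: np.ndarray, a: float, tau: float) -> np.ndarray:
    return a * np.exp(-d / tau)


def _logistic_model(d: np.ndarray, a: float, d0: float, s: float) -> np.ndarray:
    return a / (1.0 + np.exp((d - d0) / s))


def _fit_family(
    d: np.ndarray, p: np.ndarray, family: str
) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray | None, np.ndarray | None, Callable | None]:
    """Returns (fitted fn, params, covariance, raw model) for the family."""
    if family == "exponential":
        pos = p > 0
        if pos.sum() >= 2:
            slope, icpt = np.polyfit(d[pos], np.log(p[pos]), 1)
            tau0 = -1.0 / slope if slope < 0 else (d[-1] - d[0] + 1.0)
            a0 = float(np.exp(icpt))
        else:
            tau0, a0 = (d[-1] - d[0] + 1.0), max(p.max(), 1e-3)
        popt, pcov = optimize.curve_fit(
            _exp_model, d, p, p0=[a0, max(tau0, 1e-6)],
            bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
        return (lambda x: _exp_model(np.asarray(x, float), *popt)), popt, pcov, _exp_model
    if family == "logistic":
        p0 = [max(p.max(), 1e-3), float(np.median(d)), max((d[-1] - d[0]) / 10.0, 1e-3)]
        popt, pcov = optimize.curve_fit(
            _logistic_model, d, p, p0=p0,
            bounds=([0, -np.inf, 1e-9], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
        return (lambda x: _logistic_model(np.asarray(x, float), *popt)), popt, pcov, _logistic_model
    if family == "monotone_spline":
        interp = PchipInterpolator(d, p, extrapolate=False)
        return (lambda x: np.asarray(interp(np.asarray(x, float)), float)), None, None, None
    raise ValueError(f"unknown family {family!r}")


def _crossing_of_function(
    fn: Callable[[np.ndarray], np.ndarray],
    d_lo: float,
    d_hi: float,
    threshold: float,
    crossing: str,
    n_grid: int = 2001,
) -> float:
    grid = np.linspace(d_lo, d_hi, n_grid)
    vals = np.asarray(fn(grid), dtype=float)
    ok = np.isfinite(vals)
    grid, vals = grid[ok], vals[ok]
    if len(grid) < 2:
        return math.inf
    target = vals < threshold if crossing == "falls_below" else vals > threshold
    if target[0]:
        return 0.0
    idx = np.nonzero(target)[0]
    if len(idx) == 0:
        return math.inf
    j = int(idx[0])
    try:
        return float(
            optimize.brentq(lambda x: float(fn(np.array([x]))[0]) - threshold,
                            grid[j - 1], grid[j], xtol=1e-12)
        )
    except ValueError:
        return float(grid[j])


def fit_decay_curve_horizon(
    curve: ProficiencyCurve,
    family: str = "exponential",
    threshold: float = 0.6,
    crossing: str = "falls_below",
    ci_level: float = 0.95,
) -> HorizonEstimate:
    """Fit a parametric decay family to the curve, solve for the horizon.

    Least-squares fit of ``exponential`` (a*exp(-d/tau)), ``logistic``
    (a sigmoid in distance) or a shape-preserving ``monotone_spline``; the
    horizon is the fitted function's first threshold crossing. For the
    parametric families the 95% pointwise confidence envelope (delta
    method on the fit covariance) is intersected with the threshold to
    give a (lower, upper) horizon interval; the spline carries no interval.
    """
    if crossing not in _CROSSINGS:
        raise ValueError(f"crossing must be one of {sorted(_CROSSINGS)}")
    d, p = _clean_curve(curve)
    if len(d) < 4:
        raise ValueError("need at least 4 non-missing points to fit")
    try:
        fn, popt, pcov, model = _fit_family(d, p, family)
    except RuntimeError as err:  # curve_fit non-convergence
        raise RuntimeError(
            f"{family} fit failed to converge on {len(d)} points "
            f"(distance span {d[0]}..{d[-1]}): {err}"
        ) from None
    h = _crossing_of_function(fn, float(d[0]), float(d[-1]), threshold, crossing)
    interval = None
    if popt is not None and pcov is not None and np.all(np.isfinite(pcov)):
        from scipy.stats import norm

        z = norm.ppf(0.5 + ci_level / 2.0)

        def envelope(x: np.ndarray, sign: float) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            base = model(x, *popt)
            # delta method: pointwise SE from the parameter covariance
            grads = []
            for i in range(len(popt)):
                step = max(abs(popt[i]) * 1e-6, 1e-9)
                up = popt.copy(); up[i] += step
                dn = popt.copy(); dn[i] -= step
                grads.append((model(x, *up) - model(x, *dn)) / (2 * step))
            G = np.vstack(grads)
            var = np.einsum("ix,ij,jx->x", G, pcov, G)
            se = np.sqrt(np.maximum(var, 0.0))
            return base + sign * z * se

        lo_curve = _crossing_of_function(
            lambda x: envelope(x, -1.0), float(d[0]), float(d[-1]), threshold, crossing
        )
        hi_curve = _crossing_of_function(
            lambda x: envelope(x, +1.0), float(d[0]), float(d[-1]), threshold, crossing
        )
        lo, hi = sorted((lo_curve, hi_curve))
        lo = min(lo, h)
        hi = max(hi, h)
        interval = (lo, hi)
    return HorizonEstimate(
        horizon=h, threshold=threshold, crossing=crossing, unit=curve.unit,
        interval=interval,
    )


# ---------------------------------------------------------------------------
# blind spots

def _interval_partition(
    curve: ProficiencyCurve, threshold: float
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    d, p = _clean_curve(curve)
    bad_side = p < threshold if curve.higher_is_better else p > threshold
    # crossing points between consecutive samples, linearly interpolated
    edges = [float(d[0])]
    states = [bool(bad_side[0])]
    for j in range(1, len(d)):
        if bad_side[j] != bad_side[j - 1]:
            p0, p1 = p[j - 1], p[j]
            x = d[j - 1] + (threshold - p0) * (d[j] - d[j - 1]) / (p1 - p0)
            edges.append(float(x))
            states.append(bool(bad_side[j]))
    edges.append(float(d[-1]))
    bad, good = [], []
    for k in range(len(states)):
        seg = (edges[k], edges[k + 1])
        if seg[1] > seg[0]:
            (bad if states[k] else good).append(seg)
    return bad, good


def detect_blind_spots(
    curve: ProficiencyCurve, threshold: float
) -> list[tuple[float, float]]:
    """Maximal distance intervals where the curve is on the useless side.

    For a higher-is-better metric these are sub-threshold stretches —
    including interior dips (true blind spots bounded by useful windows on
    both sides) and terminal decay. Together with :func:`good_intervals`
    they partition the curve's support exactly.
    """
    bad, _ = _interval_partition(curve, threshold)
    return bad


def good_intervals(
    curve: ProficiencyCurve, threshold: float
) -> list[tuple[float, float]]:
    """Complement of :func:`detect_blind_spots` over the curve's support."""
    _, good = _interval_partition(curve, threshold)
    return good
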