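"""Lyapunov exponents and the analytic predictability time.

The largest Lyapunov exponent (LE, lambda) measures the asymptotic
exponential rate at which two infinitesimally close trajectories of a
deterministic map separate: delta_t ~ delta_0 * exp(lambda * t). A
positive exponent signals chaos and bounds predictability: given initial
uncertainty delta_0 and a required precision Delta, the predictability
time is

    T_p = (1 / lambda) * ln(Delta / delta_0),

infinite when lambda <= 0 (nearby trajectories converge, errors shrink).
T_p depends on the inverse exponent but only logarithmically on delta_0
and Delta.

Two estimation routes are provided and cross-check each other: twin-run
divergence (simulate two nearby starts, regress ln|difference| on time
before the separation saturates at the attractor's size) and the orbit
average of ln|f'(x_t)|, available whenever the map has an analytic
derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "MapSpec",
    "DivergenceSeries",
    "LyapunovEstimate",
    "logistic_map",
    "ricker_map",
    "twin_divergence",
    "estimate_le",
    "le_orbit_average",
    "horizon_from_le",
]


@dataclass(frozen=True)
class MapSpec:
    """A deterministic one-dimensional map x_{t+1} = f(x_t).

    ``fn`` and ``dfn`` take (x, param); ``domain`` is the closed interval on
    which the dynamics must stay.
    """

    name: str
    fn: Callable[[float, float], float]
    param: float
    domain: tuple[float, float]
    dfn: Callable[[float, float], float] | None = None

    def step(self, x: float) -> float:
        return self.fn(x, self.param)

    def deriv(self, x: float) -> float:
        if self.dfn is None:
            raise ValueError(f"map {self.name!r} has no analytic derivative")
        return self.dfn(x, self.param)


def logistic_map(r: float) -> MapSpec:
    """The logistic map x -> r*x*(1-x) on [0, 1]."""
    return MapSpec(
        name="logistic",
        fn=lambda x, p: p * x * (1.0 - x),
        dfn=lambda x, p: p * (1.0 - 2.0 * x),
        param=r,
        domain=(0.0, 1.0),
    )


def ricker_map(r: float) -> MapSpec:
    """The Ricker map x -> x*exp(r*(1-x)), population scaled by K."""
    return MapSpec(
        name="ricker",
        fn=lambda x, p: x * math.exp(p * (1.0 - x)),
        dfn=lambda x, p: math.exp(p * (1.0 - x)) * (1.0 - p * x),
        param=r,
        domain=(0.0, math.inf),
    )


@dataclass(frozen=True)
class DivergenceSeries:
    """ln|separation| of twin trajectories per time step."""

    times: np.ndarray
    log_separation: np.ndarray
    delta0: float
    state_range: float | None = None  # sampled extent of the reference orbit

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=int)
        ls = np.asarray(self.log_separation, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "log_separation", ls)
        if len(t) != len(ls):
            raise ValueError("times and log_separation must align")
        if self.delta0 <= 0:
            raise ValueError("delta0 must be positive")
        if len(ls) and abs(ls[0] - math.log(self.delta0)) > 1e-9:
            raise ValueError("log_separation[0] must equal ln(delta0)")


@dataclass(frozen=True)
class LyapunovEstimate:
    lam: float
    fit_range: tuple[int, int]  # [start, stop) time indices used
    stderr: float
    r_squared: float


def twin_divergence(
    map_spec: MapSpec, x0: float, delta0: float, steps: int
) -> DivergenceSeries:
    """Iterate twin trajectories from x0 and x0 + delta0; record ln|difference|.

    Stops early if the separation underflows to exactly zero. Raises if
    either trajectory leaves the map's domain, naming the offending step.
    """
    if delta0 <= 0:
        raise ValueError("delta0 must be > 0")
    lo, hi = map_spec.domain
    if not (lo <= x0 <= hi and lo <= x0 + delta0 <= hi):
        raise ValueError("x0 and x0 + delta0 must lie in the map's domain")
    x, y = float(x0), float(x0 + delta0)
    times = [0]
    log_sep = [math.log(delta0)]
    xs = [x]
    for t in range(1, steps + 1):
        x = map_spec.step(x)
        y = map_spec.step(y)
        if not (math.isfinite(x) and lo <= x <= hi):
            raise ValueError(f"reference trajectory left the domain at step {t}")
        if not (math.isfinite(y) and lo <= y <= hi):
            raise ValueError(f"perturbed trajectory left the domain at step {t}")
        xs.append(x)
        sep = abs(x - y)
        if sep == 0.0:
            break
        times.append(t)
        log_sep.append(math.log(sep))
    return DivergenceSeries(
        times=np.asarray(times),
        log_separation=np.asarray(log_sep),
        delta0=delta0,
        state_range=float(np.max(xs) - np.min(xs)),
    )


def estimate_le(
    div: DivergenceSeries, saturation_fraction: float = 0.25
) -> LyapunovEstimate:
    """Least-squares slope of ln|separation| vs time over the growth phase.

    Divergence is exponential only while the separation is small relative
    to the attractor, so the fit stops at the first step where separation
    exceeds ``saturation_fraction`` of the reference orbit's sampled range.
    """
    t = div.times
    ls = div.log_separation
    if div.state_range is not None and div.state_range > 0:
        cutoff = math.log(saturation_fraction * div.state_range)
        above = np.nonzero(ls > cutoff)[0]
        stop = int(above[0]) if len(above) else len(ls)
    else:
        stop = len(ls)
    if stop < 5:
        raise ValueError(
            f"only {stop} points before saturation; need >= 5 to estimate the exponent"
        )
    res = stats.linregress(t[:stop], ls[:stop])
    return LyapunovEstimate(
        lam=float(res.slope),
        fit_range=(int(t[0]), int(t[stop - 1]) + 1),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
    )


def le_orbit_average(
    map_spec: MapSpec, x0: float, n: int = 100_000, burn_in: int = 1000
) -> float:
    """Time-average of ln|f'(x_t)| along the orbit (independent LE route).

    Points where the derivative vanishes exactly are skipped (a set of
    measure zero on chaotic attractors).
    """
    if n < 1000:
        raise ValueError("n must be >= 1000 for a stable orbit average")
    x = float(x0)
    for _ in range(burn_in):
        x = map_spec.step(x)
    total = 0.0
    used = 0
    for _ in range(n):
        d = map_spec.deriv(x)
        if d != 0.0:
            total += math.log(abs(d))
            used += 1
        x = map_spec.step(x)
    if used == 0:
        raise ValueError("derivative vanished along the entire orbit")
    return total / used


def horizon_from_le(lam: float, delta0: float, Delta: float) -> float:
    """Predictability time T_p = ln(Delta/delta0)/lambda; infinite for lambda <= 0."""
    if delta0 <= 0:
        raise ValueError("delta0 must be > 0")
    if delta0 > Delta:
        raise ValueError(
            "delta0 > Delta: required precision exceeds initial uncertainty"
        )
    if lam <= 0:
        return math.inf
    return math.log(Delta / delta0) / lam
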