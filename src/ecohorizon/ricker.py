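"""Chaotic Ricker population dynamics and the parameter-uncertainty experiment.

The truth is a Ricker map N_{t+1} = N_t * exp(r * (1 - N_t / K_t)) in the
chaotic regime (default r = 3.0), with a linearly drifting carrying
capacity K_t = K0 + K_step * t and, optionally, demographic stochasticity
(Poisson sampling of the deterministic expectation, which makes N = 0
absorbing). The forecasting model is always deterministic: stochasticity
is a property of the true dynamics, not of the forecaster.

Forecast uncertainty is injected by drawing the predictor's r, N0 and
K_step from truncated normals centred on the truth with standard deviation
CV * value. Each replicate draws one parameter set, simulates a forecast,
and the windowed-correlation proficiency curve plus its threshold-crossing
horizon summarise how quickly chaos amplifies the mis-specification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .horizon import HorizonDistribution, HorizonEstimate, horizon_distribution, horizon_from_curve
from .proficiency import (
    ForecastEnsemble,
    ProficiencyCurve,
    Trajectory,
    nanmean_columns,
    windowed_correlation_curve,
)

__all__ = [
    "RickerConfig",
    "UncertaintySpec",
    "ExperimentResult",
    "simulate_ricker",
    "sample_predictor_config",
    "run_ricker_experiment",
]


@dataclass(frozen=True)
class RickerConfig:
    """Parameters of one Ricker simulation.

    ``k_mode="linear"`` drifts the carrying capacity as K0 + K_step*t;
    ``"step"`` applies a single jump of K_step at the midpoint (the name
    "rate of change in carrying capacity" is read as a linear trend by
    default).
    """

    r: float = 3.0
    N0: float = 50.0
    K0: float = 100.0
    K_step: float = 0.0
    steps: int = 100
    demographic_stochasticity: bool = False
    seed: int = 0
    k_mode: str = "linear"

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.N0 < 0:
            raise ValueError("N0 must be >= 0")
        if self.K0 <= 0:
            raise ValueError("K0 must be > 0")
        if self.k_mode not in {"linear", "step"}:
            raise ValueError("k_mode must be 'linear' or 'step'")
        if min(self.carrying_capacity(t) for t in range(self.steps + 1)) <= 0:
            raise ValueError("carrying capacity must stay positive over the run")

    def carrying_capacity(self, t: int) -> float:
        if self.k_mode == "linear":
            return self.K0 + self.K_step * t
        return self.K0 + (self.K_step if t >= self.steps // 2 else 0.0)


@dataclass(frozen=True)
class UncertaintySpec:
    """Coefficients of variation for the predictor's parameter draws."""

    cv_r: float = 0.0
    cv_N0: float = 0.0
    cv_Kstep: float = 0.0

    def __post_init__(self) -> None:
        if min(self.cv_r, self.cv_N0, self.cv_Kstep) < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass(frozen=True)
class ExperimentResult:
    mean_curve: ProficiencyCurve
    horizons: HorizonDistribution
    mean_curve_horizon: HorizonEstimate
    drawn_parameters: np.ndarray  # (n_reps, 3): r, N0, K_step
    truth_config: RickerConfig
    uncertainty: UncertaintySpec
    seed: int


def simulate_ricker(config: RickerConfig, rng: np.random.Generator | None = None) -> Trajectory:
    """Iterate the Ricker map for ``config.steps`` generations.

    Deterministic unless ``demographic_stochasticity`` is set, in which
    case each generation's size is a Poisson draw with the deterministic
    expectation as mean (integer-valued, N = 0 absorbing).
    """
    if config.demographic_stochasticity and rng is None:
        rng = np.random.default_rng(config.seed)
    n = float(config.N0)
    if config.demographic_stochasticity:
        n = float(np.round(n))
    values = np.empty(config.steps + 1)
    values[0] = n
    for t in range(config.steps):
        K = config.carrying_capacity(t)
        expected = n * math.exp(config.r * (1.0 - n / K)) if n > 0 else 0.0
        if not math.isfinite(expected):
            raise OverflowError(f"population became non-finite at generation {t + 1}")
        if config.demographic_stochasticity:
            n = float(rng.poisson(expected))
        else:
            n = expected
        values[t + 1] = n
    return Trajectory(
        times=np.arange(config.steps + 1, dtype=float),
        values=values,
        unit="generation",
        label="ricker",
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float | None, max_tries: int = 1000) -> float:
    if sd == 0.0:
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lower is None or x > lower:
            return x
    raise RuntimeError(
        f"truncated-normal sampling exceeded {max_tries} retries "
        f"(mean={mean}, sd={sd}, lower={lower})"
    )


def sample_predictor_config(
    truth: RickerConfig, u: UncertaintySpec, rng: np.random.Generator
) -> RickerConfig:
    """Draw a forecasting model's parameters around the truth.

    r and N0 are truncated at 0 (resampled on violation); K_step is drawn
    untruncated with SD = cv * |K_step|. The predictor is always
    deterministic regardless of the truth's stochasticity flag.
    """
    r = _truncated_normal(rng, truth.r, u.cv_r * abs(truth.r), lower=0.0)
    N0 = _truncated_normal(rng, truth.N0, u.cv_N0 * abs(truth.N0), lower=0.0)
    K_step = _truncated_normal(rng, truth.K_step, u.cv_Kstep * abs(truth.K_step), lower=None)
    return replace(
        truth, r=r, N0=N0, K_step=K_step, demographic_stochasticity=False
    )


def run_ricker_experiment(
    truth: RickerConfig,
    u: UncertaintySpec,
    n_reps: int = 200,
    window: int = 10,
    step: int = 1,
    threshold: float = 0.5,
    horizon_mode: str = "per_replicate",
    band: tuple[float, float] = (25.0, 75.0),
    seed: int = 0,
    resimulate_truth: bool = True,
) -> ExperimentResult:
    """Full forecast-horizon experiment for one uncertainty cell.

    Per replicate: draw a predictor parameter set, simulate the
    deterministic forecast, compute the moving-window correlation against
    the truth (re-simulated per replicate when the truth is stochastic and
    ``resimulate_truth`` is set), then summarise horizons either per
    replicate curve (``horizon_mode="per_replicate"``, the distribution
    route) or on the replicate-mean curve (``"mean_curve"``, the average
    proficiency route). Bit-for-bit reproducible from (configs, seed).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if horizon_mode not in {"per_replicate", "mean_curve"}:
        raise ValueError("horizon_mode must be 'per_replicate' or 'mean_curve'")
    root = np.random.SeedSequence(seed)
    draw_rng = np.random.Generator(np.random.PCG64(root.spawn(1)[0]))
    truth_seeds = root.spawn(n_reps + 1)[1:]

    global_truth = None
    if not (truth.demographic_stochasticity and resimulate_truth):
        global_truth = simulate_ricker(
            truth,
            np.random.Generator(np.random.PCG64(truth_seeds[0]))
            if truth.demographic_stochasticity
            else None,
        )

    rep_rows = []
    drawn = np.empty((n_reps, 3))
    distances = None
    for i in range(n_reps):
        if global_truth is not None:
            truth_traj = global_truth
        else:
            truth_traj = simulate_ricker(
                truth, np.random.Generator(np.random.PCG64(truth_seeds[i]))
            )
        pred_cfg = sample_predictor_config(truth, u, draw_rng)
        drawn[i] = (pred_cfg.r, pred_cfg.N0, pred_cfg.K_step)
        forecast = simulate_ricker(pred_cfg)
        curve = windowed_correlation_curve(
            ForecastEnsemble(truth=truth_traj, forecasts=(forecast,)),
            window_length=window,
            step=step,
        )
        if distances is None:
            distances = curve.distances
        rep_rows.append(curve.replicate_proficiency[0])

    rep = np.vstack(rep_rows)
    mean = nanmean_columns(rep)
    mean_curve = ProficiencyCurve(
        distances=distances,
        mean_proficiency=mean,
        metric_name="correlation",
        higher_is_better=True,
        unit="generation",
        replicate_proficiency=rep,
    )
    horizons = horizon_distribution(
        mean_curve, threshold=threshold, crossing="falls_below", band=band
    )
    mean_horizon = horizon_from_curve(mean_curve, threshold, "falls_below")
    if horizon_mode == "mean_curve":
        horizons = HorizonDistribution(
            horizons=np.array([mean_horizon.horizon]),
            threshold=threshold,
            crossing="falls_below",
            unit="generation",
            band_percentiles=band,
        )
    return ExperimentResult(
        mean_curve=mean_curve,
        horizons=horizons,
        mean_curve_horizon=mean_horizon,
        drawn_parameters=drawn,
        truth_config=truth,
        uncertainty=u,
        seed=seed,
    )
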