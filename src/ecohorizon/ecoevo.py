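"""Eco-evolutionary competition on a resource axis, and its forecast experiment.

A community of competitors lives on a one-dimensional resource/trait axis.
Species i has trait x_i; the resource distribution peaks at a fluctuating
optimum theta_t, giving a Gaussian carrying capacity

    K_i(t) = K_max * exp(-(x_i - theta_t)^2 / (2 sigma_K^2)),

and competition declines with trait distance through the Gaussian kernel
alpha_ij = exp(-(x_i - x_j)^2 / (2 sigma_alpha^2)). Abundances follow a
multispecies Ricker update

    N_i(t+1) = N_i(t) * exp(r_max * (1 - sum_j alpha_ij N_j(t) / K_i(t))),

with an extinction threshold below which a species is set (irreversibly)
to zero. When evolution is enabled, traits climb the per-capita growth
gradient at rate h (a deterministic quantitative-genetics reading of
heritable trait change):

    x_i(t+1) = x_i(t) + h * d g_i / d x_i,   g_i = r_max (1 - sum_j alpha_ij N_j / K_i).

The forecast experiment mirrors the level-of-organisation question: truth
may evolve, the forecasting model never does; the forecaster also sees the
environment only through noise of SD sigma_u. Proficiency is tracked for
two observables — one focal species' abundance and total community
biomass (unit per-capita mass, so biomass = sum of abundances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .horizon import HorizonDistribution, horizon_distribution
from .proficiency import (
    ForecastEnsemble,
    ProficiencyCurve,
    Trajectory,
    nanmean_columns,
    windowed_correlation_curve,
)

__all__ = [
    "EcoEvoConfig",
    "EnvironmentSeries",
    "CommunityTrajectory",
    "generate_environment",
    "perturb_environment",
    "simulate_ecoevo",
    "extract_observables",
    "run_ecoevo_experiment",
]


def _default_traits() -> np.ndarray:
    return np.linspace(-2.0, 2.0, 10)


@dataclass(frozen=True)
class EcoEvoConfig:
    """Parameters of the competitive community.

    Defaults: 10 species with traits equally spaced on [-2, 2], resource
    width sigma_K = 1, competition width sigma_alpha = 0.5, r_max = 1,
    K_max = 100, extinction at 1e-6 * K_max. ``h = 0`` disables evolution.
    """

    traits: np.ndarray = field(default_factory=_default_traits)
    abundances: np.ndarray | None = None
    r_max: float = 1.0
    K_max: float = 100.0
    sigma_K: float = 1.0
    sigma_alpha: float = 0.5
    h: float = 0.0
    extinction_threshold: float = 1e-4
    steps: int = 500

    def __post_init__(self) -> None:
        traits = np.asarray(self.traits, dtype=float)
        object.__setattr__(self, "traits", traits)
        if traits.ndim != 1 or len(traits) < 1:
            raise ValueError("traits must be a one-dimensional array")
        if self.abundances is None:
            ab = np.full(len(traits), self.K_max / (2.0 * len(traits)))
        else:
            ab = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", ab)
        if ab.shape != traits.shape:
            raise ValueError("abundances must align with traits")
        if np.any(ab < 0):
            raise ValueError("initial abundances must be >= 0")
        if self.sigma_K <= 0 or self.sigma_alpha <= 0:
            raise ValueError("kernel widths must be > 0")
        if self.h < 0:
            raise ValueError("evolution rate h must be >= 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")

    @property
    def n_species(self) -> int:
        return len(self.traits)

    @property
    def evolution(self) -> bool:
        return self.h > 0


@dataclass(frozen=True)
class EnvironmentSeries:
    """The resource-distribution optimum theta_t per generation."""

    theta: np.ndarray
    sd_env: float
    rho: float
    seed: int | None = None

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.ndim != 1 or len(theta) < 1:
            raise ValueError("theta must be a non-empty one-dimensional array")

    def __len__(self) -> int:
        return len(self.theta)


@dataclass(frozen=True)
class CommunityTrajectory:
    """Per-generation abundances and traits, (steps+1) x n_species."""

    abundances: np.ndarray
    traits: np.ndarray
    config: EcoEvoConfig

    @property
    def n_generations(self) -> int:
        return self.abundances.shape[0]


def generate_environment(
    sd_env: float, rho: float, steps: int, seed: int = 0
) -> EnvironmentSeries:
    """Stationary AR(1) fluctuation of the resource optimum around 0.

    The innovation variance is scaled so the marginal SD equals ``sd_env``
    for any |rho| < 1; theta_0 is drawn from the stationary distribution.
    """
    if sd_env < 0:
        raise ValueError("sd_env must be >= 0")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if sd_env == 0.0:
        return EnvironmentSeries(theta=np.zeros(steps + 1), sd_env=0.0, rho=rho, seed=seed)
    rng = np.random.default_rng(seed)
    innov_sd = sd_env * math.sqrt(1.0 - rho**2)
    theta = np.empty(steps + 1)
    theta[0] = rng.normal(0.0, sd_env)
    eps = rng.normal(0.0, innov_sd, size=steps)
    for t in range(steps):
        theta[t + 1] = rho * theta[t] + eps[t]
    return EnvironmentSeries(theta=theta, sd_env=sd_env, rho=rho, seed=seed)


def perturb_environment(
    env: EnvironmentSeries, sigma_u: float, seed: int = 0
) -> EnvironmentSeries:
    """The forecaster's imperfect view: truth plus independent N(0, sigma_u^2) noise.

    sigma_u = 0 returns a series identical to the input.
    """
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    if sigma_u == 0.0:
        return EnvironmentSeries(
            theta=env.theta.copy(), sd_env=env.sd_env, rho=env.rho, seed=seed
        )
    rng = np.random.default_rng(seed)
    noisy = env.theta + rng.normal(0.0, sigma_u, size=len(env.theta))
    return EnvironmentSeries(theta=noisy, sd_env=env.sd_env, rho=env.rho, seed=seed)


def _growth_and_gradient(
    N: np.ndarray, x: np.ndarray, theta: float, cfg: EcoEvoConfig, need_gradient: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    dx_env = x - theta
    K = cfg.K_max * np.exp(-(dx_env**2) / (2.0 * cfg.sigma_K**2))
    dxx = x[:, None] - x[None, :]
    alpha = np.exp(-(dxx**2) / (2.0 * cfg.sigma_alpha**2))
    load = alpha @ N  # sum_j alpha_ij N_j
    growth = cfg.r_max * (1.0 - load / K)
    grad = None
    if need_gradient:
        dK = -K * dx_env / cfg.sigma_K**2
        dalpha = -alpha * dxx / cfg.sigma_alpha**2
        dload = dalpha @ N
        grad = cfg.r_max * (load * dK / K**2 - dload / K)
    return growth, grad


def simulate_ecoevo(config: EcoEvoConfig, env: EnvironmentSeries) -> CommunityTrajectory:
    """Iterate the community for ``config.steps`` generations under ``env``."""
    if len(env) < config.steps + 1:
        raise ValueError("environment series shorter than the simulation")
    S = config.n_species
    N = np.empty((config.steps + 1, S))
    X = np.empty((config.steps + 1, S))
    N[0] = config.abundances
    X[0] = config.traits
    for t in range(config.steps):
        n, x = N[t], X[t]
        growth, grad = _growth_and_gradient(
            n, x, float(env.theta[t]), config, need_gradient=config.evolution
        )
        new_n = n * np.exp(growth)
        new_n[n <= 0.0] = 0.0  # extinct species never resurrect
        new_n[new_n < config.extinction_threshold] = 0.0
        if not np.all(np.isfinite(new_n)):
            raise OverflowError(f"community state became non-finite at generation {t + 1}")
        N[t + 1] = new_n
        if config.evolution:
            # extinct species carry no heritable variation; their traits freeze
            X[t + 1] = np.where(new_n > 0.0, x + config.h * grad, x)
        else:
            X[t + 1] = x
    return CommunityTrajectory(abundances=N, traits=X, config=config)


def extract_observables(
    traj: CommunityTrajectory, focal: int
) -> tuple[Trajectory, Trajectory]:
    """(focal species' abundance, total community biomass) as trajectories.

    Total biomass assumes unit per-capita mass, i.e. it is the per-
    generation sum of abundances.
    """
    S = traj.abundances.shape[1]
    if not (0 <= focal < S):
        raise IndexError(f"focal species index {focal} out of range 0..{S - 1}")
    times = np.arange(traj.n_generations, dtype=float)
    focal_traj = Trajectory(
        times=times, values=traj.abundances[:, focal], unit="generation",
        label=f"species_{focal}",
    )
    total = Trajectory(
        times=times, values=traj.abundances.sum(axis=1), unit="generation",
        label="total_biomass",
    )
    return focal_traj, total


def default_focal_species(config: EcoEvoConfig) -> int:
    """The species whose trait is nearest the long-run resource optimum (0)."""
    return int(np.argmin(np.abs(config.traits)))


def run_ecoevo_experiment(
    config: EcoEvoConfig,
    sigma_u_levels: Sequence[float],
    evolution_in_truth: bool,
    n_reps: int = 100,
    window: int = 20,
    step: int = 1,
    threshold: float = 0.5,
    sd_env: float = 1.0,
    rho: float = 0.5,
    band: tuple[float, float] = (25.0, 75.0),
    seed: int = 0,
    focal: int | None = None,
    fixed_environment: bool = False,
) -> dict[float, dict[str, HorizonDistribution]]:
    """Forecast horizons of focal abundance vs total biomass per sigma_u level.

    Environmental uncertainty has two components: intrinsic stochasticity
    of the resource optimum (the AR(1) series) and the forecaster's
    imperfect knowledge of it (``sigma_u``). By default each replicate
    draws its own true environment and truth trajectory, and the
    forecaster re-simulates the community with evolution OFF from the same
    initial state, driven by that replicate's environment plus N(0,
    sigma_u^2) perception noise — so the horizon distribution integrates
    over both components. With ``fixed_environment=True`` one true
    environment (from ``seed``) is shared by all replicates, and at
    sigma_u = 0 every replicate is identical (zero-width horizon band).

    Truth evolves iff ``evolution_in_truth``; evolution is never in the
    forecasting model. Replicates whose proficiency curve is entirely
    undefined (e.g. the focal species extinct throughout, a zero-variance
    observable) are recorded as horizon 0.

    Returns {sigma_u: {"abundance": HorizonDistribution, "biomass": ...}}.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if evolution_in_truth and config.h == 0.0:
        raise ValueError("evolution_in_truth requires config.h > 0")
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(2 * n_reps)]
    env_seeds, noise_seeds = seeds[:n_reps], seeds[n_reps:]

    truth_cfg = config if evolution_in_truth else replace(config, h=0.0)
    predictor_cfg = replace(config, h=0.0)
    focal_i = default_focal_species(config) if focal is None else focal

    if fixed_environment:
        shared_env = generate_environment(sd_env, rho, config.steps, seed=env_seeds[0])
        shared_truth = extract_observables(simulate_ecoevo(truth_cfg, shared_env), focal_i)

    results: dict[float, dict[str, HorizonDistribution]] = {}
    for sigma_u in sigma_u_levels:
        curves: dict[str, list[np.ndarray]] = {"abundance": [], "biomass": []}
        distances = None
        for i in range(n_reps):
            if fixed_environment:
                env, truth_obs = shared_env, shared_truth
            else:
                env = generate_environment(sd_env, rho, config.steps, seed=env_seeds[i])
                truth_obs = extract_observables(simulate_ecoevo(truth_cfg, env), focal_i)
            pert = perturb_environment(env, sigma_u, seed=noise_seeds[i])
            forecast = simulate_ecoevo(predictor_cfg, pert)
            fc_obs = extract_observables(forecast, focal_i)
            for name, tr, fc in (
                ("abundance", truth_obs[0], fc_obs[0]),
                ("biomass", truth_obs[1], fc_obs[1]),
            ):
                curve = windowed_correlation_curve(
                    ForecastEnsemble(truth=tr, forecasts=(fc,)),
                    window_length=window, step=step,
                )
                distances = curve.distances
                curves[name].append(curve.replicate_proficiency[0])
        level: dict[str, HorizonDistribution] = {}
        for name, rows in curves.items():
            rep = np.vstack(rows)
            mean = nanmean_columns(rep)
            pooled = ProficiencyCurve(
                distances=distances, mean_proficiency=mean,
                metric_name="correlation", higher_is_better=True,
                unit="generation", replicate_proficiency=rep,
            )
            level[name] = horizon_distribution(
                pooled, threshold=threshold, crossing="falls_below", band=band,
                on_missing="zero",
            )
        results[float(sigma_u)] = level
    return results
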