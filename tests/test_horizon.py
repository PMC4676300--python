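"""Threshold-crossing horizons, distributions, fitted curves and blind spots."""

import math

import numpy as np
import pytest

from ecohorizon.fixtures import gen_replicate_curves
from ecohorizon.horizon import (
    HorizonDistribution,
    detect_blind_spots,
    fit_decay_curve_horizon,
    good_intervals,
    horizon_distribution,
    horizon_from_curve,
)

from conftest import make_curve


def dense_scan_crossing(fn, lo, hi, threshold, crossing="falls_below", dd=1e-4):
    """Independent oracle: scan a dense grid for the first crossing."""
    grid = np.arange(lo, hi + dd, dd)
    vals = fn(grid)
    target = vals < threshold if crossing == "falls_below" else vals > threshold
    if target[0]:
        return 0.0
    idx = np.nonzero(target)[0]
    return math.inf if len(idx) == 0 else float(grid[idx[0]])


class TestHorizonFromCurve:
    def test_never_crossing_curve_has_infinite_horizon(self):
        c = make_curve([0, 5, 10], [1.0, 1.0, 1.0])
        est = horizon_from_curve(c, 0.5)
        assert est.horizon == math.inf
        assert est.is_infinite

    def test_linear_decay_interpolates_to_midpoint(self):
        c = make_curve([0.0, 10.0], [1.0, 0.0])
        assert horizon_from_curve(c, 0.5).horizon == pytest.approx(5.0)

    def test_exponential_curve_matches_dense_scan_oracle(self):
        tau = 7.0
        d = np.arange(0.0, 31.0)
        c = make_curve(d, np.exp(-d / tau))
        est = horizon_from_curve(c, 0.5)
        # oracle scans the same piecewise-linear interpolant the estimator sees
        oracle = dense_scan_crossing(
            lambda x: np.interp(x, d, np.exp(-d / tau)), 0.0, 30.0, 0.5
        )
        assert est.horizon == pytest.approx(oracle, abs=1e-3)
        # closed form tau*ln 2 as cross-check (linear interpolation bias < 0.01)
        assert est.horizon == pytest.approx(tau * math.log(2.0), abs=1e-2)

    def test_curve_starting_below_threshold_has_zero_horizon(self):
        c = make_curve([0, 1, 2], [0.2, 0.1, 0.05])
        assert horizon_from_curve(c, 0.5).horizon == 0.0

    def test_rises_above_crossing_for_improving_curves(self):
        c = make_curve([0.0, 10.0], [0.0, 1.0])
        est = horizon_from_curve(c, 0.5, crossing="rises_above")
        assert est.horizon == pytest.approx(5.0)
        flat = make_curve([0, 1, 2], [0.1, 0.2, 0.3])
        assert horizon_from_curve(flat, 0.5, "rises_above").horizon == math.inf

    def test_missing_points_are_skipped(self):
        c = make_curve([0, 1, 2, 3], [1.0, np.nan, 0.4, 0.2])
        est = horizon_from_curve(c, 0.5)
        # interpolation runs between d=0 (1.0) and d=2 (0.4)
        assert est.horizon == pytest.approx(0.0 + (0.5 - 1.0) * 2.0 / (0.4 - 1.0))

    def test_step_interpolation_returns_first_sampled_distance(self):
        c = make_curve([0.0, 10.0], [1.0, 0.0])
        assert horizon_from_curve(c, 0.5, interpolation="step").horizon == 10.0

    def test_threshold_outside_metric_range_rejected(self):
        c = make_curve([0, 1], [0.9, 0.1], metric="correlation")
        with pytest.raises(ValueError, match="outside"):
            horizon_from_curve(c, 1.5)

    def test_monotone_threshold_property(self):
        d = np.linspace(0, 20, 21)
        c = make_curve(d, np.exp(-d / 6.0))
        horizons = [horizon_from_curve(c, t).horizon for t in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(horizons, horizons[1:]))


class TestHorizonDistribution:
    def test_identical_replicates_give_zero_width_band(self):
        d = np.linspace(0, 10, 11)
        vals = np.exp(-d / 4.0)
        curves = [make_curve(d, vals) for _ in range(5)]
        dist = horizon_distribution(curves, 0.5)
        lo, hi = dist.band
        assert lo == pytest.approx(hi)
        assert dist.median == pytest.approx(hi)

    def test_odd_count_median(self):
        dist = HorizonDistribution(horizons=np.array([2.0, 4.0, 6.0, 8.0, 10.0]),
                                   threshold=0.5, crossing="falls_below")
        assert dist.median == 6.0

    def test_summary_matches_sort_oracle_on_noisy_curves(self):
        curves = gen_replicate_curves(true_horizon=5.0, noise_sd=0.05, n_reps=100, seed=3)
        dist = horizon_distribution(curves, 0.5, band=(25.0, 75.0))
        manual = np.sort([horizon_from_curve(c, 0.5).horizon for c in curves])
        assert dist.median == pytest.approx(float(np.median(manual)))
        assert dist.band[0] == pytest.approx(float(np.percentile(manual, 25.0)))
        assert dist.band[1] == pytest.approx(float(np.percentile(manual, 75.0)))

    def test_infinities_rank_above_finite_values(self):
        dist = HorizonDistribution(
            horizons=np.array([1.0, 2.0, math.inf, math.inf, math.inf]),
            threshold=0.5, crossing="falls_below",
        )
        assert dist.median == math.inf
        assert dist.n_infinite == 3
        assert dist.finite_mean == pytest.approx(1.5)

    def test_curve_with_replicate_matrix_accepted(self):
        d = np.linspace(0, 10, 11)
        rep = np.vstack([np.exp(-d / tau) for tau in (3.0, 4.0, 5.0)])
        c = make_curve(d, rep.mean(axis=0), replicate_proficiency=rep)
        dist = horizon_distribution(c, 0.5)
        assert len(dist.horizons) == 3
        assert np.all(np.diff(dist.horizons) > 0)  # larger tau crosses later


class TestFitDecayCurveHorizon:
    def test_noiseless_exponential_recovery(self):
        d = np.linspace(0, 20, 30)
        c = make_curve(d, np.exp(-d / 7.0))
        est = fit_decay_curve_horizon(c, "exponential", threshold=0.6)
        assert est.horizon == pytest.approx(7.0 * math.log(1 / 0.6), abs=1e-6)

    def test_curve_above_threshold_everywhere_is_infinite(self):
        d = np.linspace(0, 10, 20)
        c = make_curve(d, 0.9 + 0.05 * np.exp(-d))
        est = fit_decay_curve_horizon(c, "exponential", threshold=0.5)
        assert est.horizon == math.inf

    def test_noisy_fit_horizon_lies_inside_its_own_interval(self):
        rng = np.random.default_rng(7)
        d = np.linspace(0, 20, 30)
        c = make_curve(d, np.exp(-d / 7.0) + rng.normal(0, 0.05, 30))
        est = fit_decay_curve_horizon(c, "exponential", threshold=0.6)
        lo, hi = est.interval
        assert lo <= est.horizon <= hi

    def test_logistic_family_noiseless_recovery(self):
        d = np.linspace(0, 20, 40)
        vals = 1.0 / (1.0 + np.exp((d - 8.0) / 2.0))
        c = make_curve(d, vals)
        est = fit_decay_curve_horizon(c, "logistic", threshold=0.5)
        assert est.horizon == pytest.approx(8.0, abs=1e-6)

    def test_monotone_spline_interpolates_crossing(self):
        d = np.linspace(0, 10, 11)
        c = make_curve(d, 1.0 - d / 10.0)
        est = fit_decay_curve_horizon(c, "monotone_spline", threshold=0.5)
        assert est.horizon == pytest.approx(5.0, abs=1e-9)
        assert est.interval is None

    def test_too_few_points_rejected(self):
        c = make_curve([0, 1, 2], [1.0, 0.5, 0.2])
        with pytest.raises(ValueError, match="at least 4"):
            fit_decay_curve_horizon(c, "exponential", threshold=0.5)


class TestBlindSpots:
    def test_monotone_decay_has_single_terminal_bad_interval(self):
        d = np.linspace(0, 10, 101)
        c = make_curve(d, 1.0 - d / 10.0)
        spots = detect_blind_spots(c, 0.5)
        assert len(spots) == 1
        assert spots[0][0] == pytest.approx(5.0)
        assert spots[0][1] == pytest.approx(10.0)

    def test_interior_dip_matches_dense_scan_oracle(self):
        fn = lambda x: 1.0 - 0.8 * np.exp(-((x - 5.0) ** 2) / 2.0)
        d = np.linspace(0, 10, 201)
        c = make_curve(d, fn(d))
        spots = detect_blind_spots(c, 0.5)
        assert len(spots) == 1
        lo_oracle = dense_scan_crossing(fn, 0.0, 10.0, 0.5)
        grid = np.arange(0, 10, 1e-4)
        above = grid[(fn(grid) >= 0.5) & (grid > lo_oracle)]
        hi_oracle = above[0]
        assert spots[0][0] == pytest.approx(lo_oracle, abs=1e-3)
        assert spots[0][1] == pytest.approx(hi_oracle, abs=1e-3)

    def test_curve_entirely_above_threshold_has_no_blind_spots(self):
        c = make_curve([0, 1, 2], [0.9, 0.8, 0.85])
        assert detect_blind_spots(c, 0.5) == []

    def test_good_and_bad_intervals_partition_support(self):
        rng = np.random.default_rng(5)
        d = np.linspace(0, 20, 80)
        c = make_curve(d, 0.5 + 0.4 * np.sin(d) + rng.normal(0, 0.05, 80))
        bad = detect_blind_spots(c, 0.5)
        good = good_intervals(c, 0.5)
        segs = sorted(bad + good)
        assert segs[0][0] == pytest.approx(d[0])
        assert segs[-1][1] == pytest.approx(d[-1])
        for (a, b), (c2, _) in zip(segs, segs[1:]):
            assert b == pytest.approx(c2)  # no overlap, no gap
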