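"""Readers, writers and provenance helpers for the package's file formats.

Formats are deliberately plain: trajectory CSV (``time,value[,replicate]``),
curve CSV (``distance,mean[,lower,upper][,rep_*]``), site-by-species CSV
plus a coordinates CSV, Newick trees, host-use CSV, and JSON horizon
reports. JSON has no infinity literal, so infinite horizons are serialised
as the string ``"inf"`` with an ``is_infinite`` sidecar flag. Every report
records the seed and a sha256 digest of the canonicalised configuration so
any stochastic output is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any, Sequence

import dendropy
import numpy as np
import pandas as pd

from .dimensional import HostUseRecord, SiteBySpeciesMatrix
from .horizon import HorizonDistribution, HorizonEstimate
from .proficiency import ForecastEnsemble, ProficiencyCurve, Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectory",
    "write_curve",
    "read_curve",
    "read_community",
    "write_community",
    "read_tree",
    "read_host_use",
    "write_host_use",
    "config_digest",
    "horizon_report",
    "write_report",
]


def read_trajectories(
    path: str | Path, unit: str = "generation", truth_label: str | None = None
) -> Trajectory | list[Trajectory] | ForecastEnsemble:
    """Read a trajectory CSV (columns ``time,value[,replicate]``).

    Without a replicate column a single Trajectory is returned. With one,
    a list of per-replicate trajectories is returned — unless
    ``truth_label`` names one replicate, in which case a ForecastEnsemble
    is built with the remaining replicates as forecasts.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not {"time", "value"} <= cols:
        raise ValueError(f"{path}: CSV must have 'time' and 'value' columns")

    def build(sub: pd.DataFrame, label: str) -> Trajectory:
        times = sub["time"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if len(bad):
            raise ValueError(
                f"{path}: non-monotone time at data row {int(bad[0]) + 2}"
            )
        return Trajectory(
            times=times, values=sub["value"].to_numpy(dtype=float),
            unit=unit, label=label,
        )

    if "replicate" not in cols:
        return build(df, Path(path).stem)
    groups = {str(k): g for k, g in df.groupby("replicate", sort=False)}
    if truth_label is None:
        return [build(g, k) for k, g in groups.items()]
    if truth_label not in groups:
        raise ValueError(f"{path}: no replicate labelled {truth_label!r}")
    truth = build(groups.pop(truth_label), truth_label)
    forecasts = tuple(build(g, k) for k, g in groups.items())
    return ForecastEnsemble(truth=truth, forecasts=forecasts)


def write_trajectory(traj: Trajectory | Sequence[Trajectory], path: str | Path) -> None:
    """Write one or several trajectories to the trajectory CSV format."""
    if isinstance(traj, Trajectory):
        pd.DataFrame({"time": traj.times, "value": traj.values}).to_csv(path, index=False)
        return
    frames = [
        pd.DataFrame({"time": t.times, "value": t.values,
                      "replicate": t.label or f"rep_{i}"})
        for i, t in enumerate(traj)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_curve(curve: ProficiencyCurve, path: str | Path, include_replicates: bool = False) -> None:
    data: dict[str, Any] = {"distance": curve.distances, "mean": curve.mean_proficiency}
    if curve.band is not None:
        data["lower"], data["upper"] = curve.band
    if include_replicates and curve.replicate_proficiency is not None:
        for i, row in enumerate(curve.replicate_proficiency):
            data[f"rep_{i}"] = row
    pd.DataFrame(data).to_csv(path, index=False)


def read_curve(
    path: str | Path, metric_name: str = "correlation",
    higher_is_better: bool = True, unit: str = "generation",
) -> ProficiencyCurve:
    df = pd.read_csv(path)
    if not {"distance", "mean"} <= set(df.columns):
        raise ValueError(f"{path}: curve CSV must have 'distance' and 'mean' columns")
    band = None
    if {"lower", "upper"} <= set(df.columns):
        band = (df["lower"].to_numpy(float), df["upper"].to_numpy(float))
    reps = [c for c in df.columns if c.startswith("rep_")]
    rep = df[reps].to_numpy(float).T if reps else None
    return ProficiencyCurve(
        distances=df["distance"].to_numpy(float),
        mean_proficiency=df["mean"].to_numpy(float),
        metric_name=metric_name, higher_is_better=higher_is_better,
        unit=unit, replicate_proficiency=rep, band=band,
    )


def read_community(matrix_path: str | Path, coords_path: str | Path) -> SiteBySpeciesMatrix:
    """Read a site-by-species CSV (rows = sites) and a ``site,x,y[,crs]`` CSV."""
    mat = pd.read_csv(matrix_path, index_col=0)
    coords = pd.read_csv(coords_path)
    if "site" not in coords.columns or not {"x", "y"} <= set(coords.columns):
        raise ValueError(f"{coords_path}: needs columns site,x,y")
    coords = coords.set_index("site")
    mat_sites = [str(s) for s in mat.index]
    coord_sites = {str(s) for s in coords.index}
    missing = [s for s in mat_sites if s not in coord_sites]
    extra = [str(s) for s in coords.index if str(s) not in set(mat_sites)]
    if missing or extra:
        raise ValueError(
            f"site ids mismatch between {matrix_path} and {coords_path}: "
            f"missing coordinates for {missing}, extra coordinates for {extra}"
        )
    ab = mat.to_numpy(dtype=float)
    if np.any(ab < 0):
        raise ValueError(f"{matrix_path}: negative abundance")
    lonlat = "crs" in coords.columns and (coords["crs"] == "lonlat").any()
    xy = coords.loc[[s for s in mat.index], ["x", "y"]].to_numpy(dtype=float)
    return SiteBySpeciesMatrix(
        site_ids=tuple(mat_sites), coords=xy, abundances=ab,
        species=tuple(str(c) for c in mat.columns), lonlat=bool(lonlat),
    )


def write_community(m: SiteBySpeciesMatrix, matrix_path: str | Path, coords_path: str | Path) -> None:
    pd.DataFrame(m.abundances, index=list(m.site_ids), columns=list(m.species)).to_csv(matrix_path)
    cdf = pd.DataFrame({"site": list(m.site_ids), "x": m.coords[:, 0], "y": m.coords[:, 1]})
    if m.lonlat:
        cdf["crs"] = "lonlat"
    cdf.to_csv(coords_path, index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree, requiring unique tip labels and branch lengths."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as err:  # dendropy raises its own error classes
        if "duplicate" in str(err).lower():
            raise ValueError(f"{path}: duplicate tip labels") from err
        raise
    labels = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(f"{path}: missing branch lengths (no silent default applied)")
    return tree


def read_host_use(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"herbivore", "plant", "used"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: host-use CSV needs columns {sorted(needed)}")
    if not df["used"].isin((0, 1)).all():
        raise ValueError(f"{path}: 'used' must be binary")
    return df


def write_host_use(records: Sequence[HostUseRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def _canonical(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _canonical(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_digest(config: Any) -> str:
    """Stable sha256 digest of a canonicalised configuration object."""
    payload = json.dumps(_canonical(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonify_horizon(h: float) -> dict[str, Any]:
    return {"value": "inf" if math.isinf(h) else h, "is_infinite": bool(math.isinf(h))}


def horizon_report(
    estimate: HorizonEstimate | None = None,
    distribution: HorizonDistribution | None = None,
    metric: str = "correlation",
    seed: int | None = None,
    config: Any = None,
    extra: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble the standard JSON horizon report."""
    report: dict[str, Any] = {"metric": metric}
    src = estimate if estimate is not None else distribution
    if src is None:
        raise ValueError("need an estimate or a distribution")
    report["threshold"] = src.threshold
    report["crossing"] = src.crossing
    report["unit"] = src.unit
    if estimate is not None:
        report["horizon"] = _jsonify_horizon(estimate.horizon)
        if estimate.interval is not None:
            report["interval"] = [_jsonify_horizon(v) for v in estimate.interval]
    if distribution is not None:
        lo, hi = distribution.band
        report["median_horizon"] = _jsonify_horizon(distribution.median)
        report["band"] = [_jsonify_horizon(lo), _jsonify_horizon(hi)]
        report["band_percentiles"] = list(distribution.band_percentiles)
        report["finite_mean"] = _jsonify_horizon(distribution.finite_mean)
        report["n_replicates"] = int(len(distribution.horizons))
        report["n_infinite"] = distribution.n_infinite
    if seed is not None:
        report["seed"] = int(seed)
    if config is not None:
        report["config_digest"] = config_digest(config)
    if extra:
        report.update(extra)
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
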