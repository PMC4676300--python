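"""Forecast horizons along space and phylogeny.

Two comparative pipelines:

* **Distance decay of community similarity** — similarity between pairs of
  sites (Sørensen on presence sets, or Pearson correlation of square-root
  transformed abundances) binned by geographic distance gives a
  proficiency-vs-km curve; the spatial horizon is where it falls below the
  usefulness threshold.

* **Phylogenetic host-use prediction** — a binomial GLM predicts whether a
  herbivore uses a plant from the herbivore's host breadth and the plant's
  (minimum) patristic distance to another known host. Predictions are cut
  into phylogenetic-distance slices; per-slice AUC gives a proficiency-vs-
  MYA curve. Because discrimination improves with distance, the horizon is
  a *rising* crossing: the distance beyond which forecasts become useful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .proficiency import ProficiencyCurve

__all__ = [
    "SiteBySpeciesMatrix",
    "HostUseRecord",
    "HostUseModel",
    "SliceCurve",
    "sorensen",
    "sqrt_abundance_correlation",
    "distance_decay_curve",
    "patristic_distances",
    "fit_host_use_model",
    "predict_host_use",
    "auc",
    "slice_proficiency_curve",
]

_EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class SiteBySpeciesMatrix:
    """Abundance counts per site x species with site coordinates.

    Coordinates are planar km unless ``lonlat`` is set, in which case they
    are (longitude, latitude) degrees and pair distances use the haversine
    great-circle formula (reported in km either way).
    """

    site_ids: tuple[str, ...]
    coords: np.ndarray
    abundances: np.ndarray
    species: tuple[str, ...]
    lonlat: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        ab = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "abundances", ab)
        n = len(self.site_ids)
        if coords.shape != (n, 2):
            raise ValueError("coords must be n_sites x 2")
        if ab.shape[0] != n or ab.shape[1] != len(self.species):
            raise ValueError("abundances must be n_sites x n_species")
        if np.any(ab < 0):
            raise ValueError("abundances must be >= 0")
        if len({tuple(c) for c in coords}) != n:
            raise ValueError("site coordinates must be unique")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def pairwise_distances_km(self) -> np.ndarray:
        if not self.lonlat:
            return squareform(pdist(self.coords))
        lon = np.radians(self.coords[:, 0])
        lat = np.radians(self.coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass(frozen=True)
class HostUseRecord:
    """One herbivore-plant pair: outcome plus the two model covariates."""

    herbivore: str
    plant: str
    used: int
    breadth: int
    distance: float  # min patristic distance (MYA) to a known host

    def __post_init__(self) -> None:
        if self.used not in (0, 1):
            raise ValueError("used must be 0 or 1")
        if self.breadth < 1:
            raise ValueError("host breadth must be >= 1")
        if self.distance < 0:
            raise ValueError("phylogenetic distance must be >= 0")


@dataclass(frozen=True)
class HostUseModel:
    """Fitted binomial GLM on the logit scale."""

    intercept: float
    beta_breadth: float
    beta_distance: float
    se: tuple[float, float, float]
    converged: bool
    log_breadth: bool = False
    n_records: int = 0


@dataclass(frozen=True)
class SliceCurve:
    """Per-slice AUC over phylogenetic distance slices."""

    midpoints: np.ndarray
    auc: np.ndarray
    counts: np.ndarray
    edges: np.ndarray
    scheme: str

    def to_proficiency_curve(self) -> ProficiencyCurve:
        return ProficiencyCurve(
            distances=self.midpoints,
            mean_proficiency=self.auc,
            metric_name="auc",
            higher_is_better=True,
            unit="MYA",
        )


def sorensen(a: Iterable, b: Iterable) -> float:
    """Sørensen similarity 2|A∩B| / (|A|+|B|) of two species sets.

    Interpretable as the fraction of correctly predicted occurrences when
    one community is used to forecast the other.
    """
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("Sørensen similarity undefined for two empty sets")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def sqrt_abundance_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation of square-root transformed abundance vectors.

    Returns NaN (missing) when either transformed vector is constant.
    """
    x = np.sqrt(np.asarray(a, dtype=float))
    y = np.sqrt(np.asarray(b, dtype=float))
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length abundance vectors of length >= 3")
    sx = x - x.mean()
    sy = y - y.mean()
    vx, vy = float(sx @ sx), float(sy @ sy)
    if vx == 0.0 or vy == 0.0:
        return math.nan
    return float(np.clip(sx @ sy / math.sqrt(vx * vy), -1.0, 1.0))


def distance_decay_curve(
    m: SiteBySpeciesMatrix,
    metric: str = "sorensen",
    bins: int | Sequence[float] = 10,
) -> ProficiencyCurve:
    """Similarity of all site pairs binned by geographic distance.

    Per-bin mean similarity forms the curve, labelled at bin midpoints in
    km; empty bins (and bins whose every pair is undefined) are missing
    points.
    """
    if metric not in {"sorensen", "sqrt_pearson"}:
        raise ValueError("metric must be 'sorensen' or 'sqrt_pearson'")
    if m.n_sites < 2:
        raise ValueError("need at least 2 sites")
    D = m.pairwise_distances_km()
    iu, ju = np.triu_indices(m.n_sites, k=1)
    dists = D[iu, ju]
    sims = np.empty(len(dists))
    for k, (i, j) in enumerate(zip(iu, ju)):
        if metric == "sorensen":
            pres_i = np.nonzero(m.abundances[i] > 0)[0]
            pres_j = np.nonzero(m.abundances[j] > 0)[0]
            if len(pres_i) == 0 and len(pres_j) == 0:
                sims[k] = math.nan
            else:
                sims[k] = sorensen(pres_i, pres_j)
        else:
            sims[k] = sqrt_abundance_correlation(m.abundances[i], m.abundances[j])
    if np.isscalar(bins):
        edges = np.linspace(dists.min(), dists.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if edges[0] > dists.min() or edges[-1] < dists.max():
            raise ValueError("bin edges must cover the observed distance range")
    idx = np.clip(np.digitize(dists, edges) - 1, 0, len(edges) - 2)
    mids = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(len(mids), math.nan)
    for b in range(len(mids)):
        vals = sims[(idx == b) & ~np.isnan(sims)]
        if len(vals):
            means[b] = vals.mean()
    return ProficiencyCurve(
        distances=mids,
        mean_proficiency=means,
        metric_name=metric if metric == "sorensen" else "sqrt_pearson",
        higher_is_better=True,
        unit="km",
    )


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric matrix of summed branch lengths between every tip pair (MYA)."""
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label is None:
            raise ValueError("every tip must be labelled")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def _design_matrix(records: Sequence[HostUseRecord], log_breadth: bool) -> tuple[np.ndarray, np.ndarray]:
    breadth = np.array([r.breadth for r in records], dtype=float)
    if log_breadth:
        breadth = np.log(breadth)
    dist = np.array([r.distance for r in records], dtype=float)
    X = np.column_stack([np.ones(len(records)), breadth, dist])
    y = np.array([r.used for r in records], dtype=float)
    return X, y


def fit_host_use_model(
    records: Sequence[HostUseRecord],
    log_breadth: bool = False,
    ridge_on_separation: bool = False,
) -> HostUseModel:
    """Maximum-likelihood logistic regression of use on breadth and distance.

    Fitted by IRLS (statsmodels binomial GLM, deviance tolerance 1e-8, up
    to 50 iterations). Complete separation raises unless
    ``ridge_on_separation`` enables a tiny (1e-6) L2 penalty fallback.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    X, y = _design_matrix(records, log_breadth)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    glm = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"):
            res = glm.fit(maxiter=50, tol=1e-8)
        params = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        converged = bool(res.converged)
        if not np.all(np.isfinite(se)) or np.any(np.abs(params) > 1e3):
            raise sm.tools.sm_exceptions.PerfectSeparationError("separation suspected")
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as err:
        if not ridge_on_separation:
            raise RuntimeError(
                "logistic fit failed (likely complete separation); "
                "retry with ridge_on_separation=True for a penalised fallback"
            ) from err
        res = glm.fit_regularized(alpha=1e-6, L1_wt=0.0)
        params = np.asarray(res.params, dtype=float)
        se = np.full(3, math.nan)
        converged = True
    return HostUseModel(
        intercept=float(params[0]),
        beta_breadth=float(params[1]),
        beta_distance=float(params[2]),
        se=(float(se[0]), float(se[1]), float(se[2])),
        converged=converged,
        log_breadth=log_breadth,
        n_records=len(records),
    )


def predict_host_use(
    model: HostUseModel, records: Sequence[HostUseRecord]
) -> np.ndarray:
    """Inverse-logit of the fitted linear predictor for each record."""
    X, _ = _design_matrix(records, model.log_breadth)
    eta = X @ np.array([model.intercept, model.beta_breadth, model.beta_distance])
    return 1.0 / (1.0 + np.exp(-eta))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank statistic (ties count 1/2).

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # average ranks handle ties as 1/2 wins
    r_pos = float(np.sum(ranks[y == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def slice_proficiency_curve(
    predictions: Sequence[float],
    labels: Sequence[int],
    distances: Sequence[float],
    n_slices: int = 12,
    scheme: str = "equal_count",
) -> SliceCurve:
    """AUC within each phylogenetic-distance slice.

    ``equal_count`` slices at distance quantiles (default: protects each
    slice's AUC from tiny classes); ``equal_width`` slices the distance
    range evenly. Slices lacking both outcome classes yield a missing AUC.
    The resulting curve rises with distance for host-use data and is meant
    for ``horizon_from_curve(..., crossing="rises_above")``.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    d = np.asarray(distances, dtype=float)
    if not (len(p) == len(y) == len(d)):
        raise ValueError("predictions, labels and distances must align")
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    if scheme not in {"equal_count", "equal_width"}:
        raise ValueError("scheme must be 'equal_count' or 'equal_width'")
    if d.max() == d.min():
        raise ValueError("degenerate distance range: all records at one distance")
    if scheme == "equal_count":
        qs = np.linspace(0, 1, n_slices + 1)
        edges = np.unique(np.quantile(d, qs))
        # tied distances can leave edges closer than float resolution; merge them
        span = d.max() - d.min()
        keep = np.concatenate(([True], np.diff(edges) > 1e-9 * span))
        edges = edges[keep]
        if len(edges) < 3:
            raise ValueError("distance distribution too concentrated to slice")
    else:
        edges = np.linspace(d.min(), d.max(), n_slices + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    mids = 0.5 * (edges[:-1] + edges[1:])
    aucs = np.full(len(mids), math.nan)
    counts = np.zeros(len(mids), dtype=int)
    any_defined = False
    for b in range(len(mids)):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b] == 0:
            continue
        yy = y[mask]
        if len(np.unique(yy)) < 2:
            continue
        aucs[b] = auc(p[mask], yy)
        any_defined = True
    if not any_defined:
        raise ValueError("no slice contains both outcome classes")
    return SliceCurve(midpoints=mids, auc=aucs, counts=counts, edges=edges, scheme=scheme)
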