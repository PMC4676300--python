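"""Synthetic data generators with the statistical structure the comparative
pipelines assume.

These are first-class, seeded, pure functions of their spec: spatial
communities whose compositional similarity decays with distance at a known
scale, pure-birth (Yule) plant phylogenies, host-use tables drawn from a
logistic law with known coefficients, and replicate proficiency curves
whose noiseless version crosses a stated threshold at a known horizon.
Because every generator's parameters are known, each downstream estimator
gets a parameter-recovery test instead of an external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .dimensional import HostUseRecord, SiteBySpeciesMatrix, patristic_distances
from .proficiency import ProficiencyCurve

__all__ = [
    "SpatialFixtureSpec",
    "PhyloFixtureSpec",
    "gen_spatial_communities",
    "gen_yule_tree",
    "gen_host_use_table",
    "gen_replicate_curves",
]


@dataclass(frozen=True)
class SpatialFixtureSpec:
    """Recipe for a site-by-species matrix with distance-decaying similarity.

    Each species gets a random range centre in a square arena and occupies
    a disc whose radius is drawn around ``decay_scale_km`` (uniform within
    +/-50%); occupancy inside the range is near-certain (``p_inside``) and
    outside it a rare background event (``p_outside``), so two nearby
    sites share almost all species while distant sites share few — the
    similarity of site pairs decays on the generating range scale.
    Abundances on occupied cells are log-normal with a median that decays
    from the range centre, giving correlation decay as well.
    """

    n_sites: int = 30
    n_species: int = 40
    arena_km: float = 1000.0
    decay_scale_km: float = 250.0
    p_inside: float = 0.95
    p_outside: float = 0.02
    log_abundance_mean: float = 3.0
    log_abundance_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_species < 2:
            raise ValueError("need at least 2 sites and 2 species")
        if self.decay_scale_km <= 0:
            raise ValueError("decay scale must be > 0")


@dataclass(frozen=True)
class PhyloFixtureSpec:
    """Recipe for a host-use table over a pure-birth plant phylogeny.

    ``beta0``, ``beta_breadth`` and ``beta_distance`` are the true logit
    coefficients of the generative use law applied to (host breadth,
    minimum patristic distance to a seed host). Seed hosts cluster within
    clades with probability ``clade_prob`` to emulate family-level host
    specialisation. On top of the logistic law, a record's outcome is
    replaced by a fair coin with probability ``idiosyncrasy *
    exp(-distance/idiosyncrasy_scale)``: host use among close relatives of
    a known host is idiosyncratic (plant chemistry varies within clades)
    while use across distant clades is reliably determined — this is what
    makes forecast proficiency *rise* with phylogenetic distance.
    """

    n_plant_taxa: int = 60
    birth_rate: float = 0.05
    n_herbivores: int = 80
    beta0: float = -0.5
    beta_breadth: float = 0.6
    beta_distance: float = -0.01
    mean_breadth: float = 3.0
    clade_prob: float = 0.8
    idiosyncrasy: float = 0.95
    idiosyncrasy_scale: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plant_taxa < 4:
            raise ValueError("need at least 4 plant taxa")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be > 0")
        if not 0 <= self.clade_prob <= 1:
            raise ValueError("clade_prob must lie in [0, 1]")


def gen_spatial_communities(spec: SpatialFixtureSpec) -> SiteBySpeciesMatrix:
    """Draw a site-by-species abundance matrix per the spatial recipe."""
    rng = np.random.default_rng(spec.seed)
    sites = rng.uniform(0.0, spec.arena_km, size=(spec.n_sites, 2))
    centres = rng.uniform(0.0, spec.arena_km, size=(spec.n_species, 2))
    radii = rng.uniform(0.5, 1.5, size=spec.n_species) * spec.decay_scale_km
    d = np.linalg.norm(sites[:, None, :] - centres[None, :, :], axis=2)
    occ_p = np.where(d < radii[None, :], spec.p_inside, spec.p_outside)
    occupied = rng.random(occ_p.shape) < occ_p
    log_mu = spec.log_abundance_mean - d / spec.decay_scale_km
    abundance = np.exp(rng.normal(log_mu, spec.log_abundance_sd))
    counts = np.where(occupied, np.maximum(1, np.round(abundance)), 0.0)
    return SiteBySpeciesMatrix(
        site_ids=tuple(f"site_{i}" for i in range(spec.n_sites)),
        coords=sites,
        abundances=counts,
        species=tuple(f"sp_{j}" for j in range(spec.n_species)),
        lonlat=False,
    )


def gen_yule_tree(n_taxa: int, birth_rate: float, seed: int = 0) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth tree, branch lengths in time units.

    Starting from two lineages, each of the k current lineages splits at
    total rate k*birth_rate; the lineage that splits is chosen uniformly.
    When n_taxa lineages exist all are extended to the present, so every
    tip sits at the same depth. Tips are labelled t1..tn deterministically.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    now = 0.0
    root = tree.seed_node
    left = root.new_child()
    right = root.new_child()
    births = {left: now, right: now}
    active = [left, right]
    while len(active) < n_taxa:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(int(rng.integers(len(active))))
        parent.edge.length = now - births.pop(parent)
        for _ in range(2):
            child = parent.new_child()
            births[child] = now
            active.append(child)
    # waiting time while n lineages exist, then extend all to the present
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length = now - births[node]
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{k + 1}")
    root.edge.length = 0.0
    return tree


def gen_host_use_table(
    spec: PhyloFixtureSpec, tree: dendropy.Tree
) -> list[HostUseRecord]:
    """Draw herbivore-plant use records from the logistic generative law.

    Per herbivore: a breadth b >= 1 is drawn (1 + Poisson), b seed hosts
    are chosen — the first uniformly, subsequent ones from the nearest
    relatives of an existing host with probability ``clade_prob`` (else
    uniformly) — and every remaining plant's use is Bernoulli with
    logit(p) = beta0 + beta_breadth*b + beta_distance*d, where d is the
    minimum patristic distance to any seed host.
    """
    rng = np.random.default_rng(spec.seed)
    pdm = patristic_distances(tree)
    plants = list(pdm.index)
    D = pdm.to_numpy()
    n_plants = len(plants)
    records: list[HostUseRecord] = []
    for h in range(spec.n_herbivores):
        breadth = 1 + int(rng.poisson(spec.mean_breadth - 1.0))
        breadth = min(breadth, n_plants - 1)
        hosts = [int(rng.integers(n_plants))]
        while len(hosts) < breadth:
            if rng.random() < spec.clade_prob:
                anchor = hosts[int(rng.integers(len(hosts)))]
                order = np.argsort(D[anchor])
                candidates = [int(i) for i in order if i not in hosts and i != anchor]
                nxt = candidates[0]
            else:
                choices = [i for i in range(n_plants) if i not in hosts]
                nxt = int(choices[int(rng.integers(len(choices)))])
            hosts.append(nxt)
        host_set = set(hosts)
        for j in range(n_plants):
            if j in host_set:
                continue
            dist = float(D[j, hosts].min())
            eta = spec.beta0 + spec.beta_breadth * breadth + spec.beta_distance * dist
            p = 1.0 / (1.0 + math.exp(-eta))
            # short-range idiosyncrasy: close relatives are hit-or-miss
            flip = spec.idiosyncrasy * math.exp(-dist / spec.idiosyncrasy_scale)
            p = (1.0 - flip) * p + flip * 0.5
            records.append(
                HostUseRecord(
                    herbivore=f"h{h}",
                    plant=plants[j],
                    used=int(rng.random() < p),
                    breadth=breadth,
                    distance=dist,
                )
            )
    return records


def gen_replicate_curves(
    true_horizon: float,
    family: str = "exponential",
    noise_sd: float = 0.05,
    n_reps: int = 20,
    threshold: float = 0.5,
    distances: np.ndarray | None = None,
    seed: int = 0,
) -> list[ProficiencyCurve]:
    """Noisy replicate curves whose noiseless version crosses ``threshold``
    exactly at ``true_horizon``.

    ``exponential``: p(d) = exp(-d/tau) with tau chosen so
    p(true_horizon) = threshold. ``linear``: straight decay from 1 at 0 to
    threshold at true_horizon, continuing at the same slope.
    """
    if true_horizon <= 0:
        raise ValueError("true_horizon must be > 0")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if distances is None:
        distances = np.linspace(0.0, 3.0 * true_horizon, 31)
    distances = np.asarray(distances, dtype=float)
    if not (distances[0] <= true_horizon <= distances[-1]):
        raise ValueError("true_horizon must lie within the distance support")
    if family == "exponential":
        tau = true_horizon / math.log(1.0 / threshold)
        base = np.exp(-distances / tau)
    elif family == "linear":
        slope = (threshold - 1.0) / true_horizon
        base = 1.0 + slope * distances
    else:
        raise ValueError("family must be 'exponential' or 'linear'")
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_reps):
        vals = base + rng.normal(0.0, noise_sd, size=len(distances))
        curves.append(
            ProficiencyCurve(
                distances=distances,
                mean_proficiency=vals,
                metric_name="synthetic",
                higher_is_better=True,
                unit="arbitrary",
            )
        )
    return curves
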