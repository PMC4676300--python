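"""Spatial similarity decay and phylogenetic host-use prediction."""

import math
from collections import deque

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecohorizon.dimensional import (
    HostUseRecord,
    SiteBySpeciesMatrix,
    auc,
    distance_decay_curve,
    fit_host_use_model,
    patristic_distances,
    predict_host_use,
    slice_proficiency_curve,
    sorensen,
    sqrt_abundance_correlation,
)
from ecohorizon.fixtures import PhyloFixtureSpec, gen_host_use_table, gen_yule_tree


def bfs_patristic(tree: dendropy.Tree) -> dict:
    """Independent graph-traversal oracle for tip-to-tip path lengths."""
    adj = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None or edge.length is None:
            continue
        adj.setdefault(edge.tail_node, []).append((edge.head_node, edge.length))
        adj.setdefault(edge.head_node, []).append((edge.tail_node, edge.length))
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    out = {}
    for label, start in leaves.items():
        dist = {start: 0.0}
        q = deque([start])
        while q:
            node = q.popleft()
            for nb, w in adj.get(node, []):
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    q.append(nb)
        for other, leaf in leaves.items():
            out[(label, other)] = dist[leaf]
    return out


class TestSimilarities:
    def test_sorensen_identity_disjoint_and_enumeration(self):
        assert sorensen({"a", "b"}, {"a", "b"}) == 1.0
        assert sorensen({"a"}, {"b"}) == 0.0
        assert sorensen({"s1", "s2", "s3"}, {"s2", "s3", "s4"}) == pytest.approx(4 / 6)

    def test_sorensen_symmetric_and_rejects_empty(self):
        a, b = {"x", "y"}, {"y", "z", "w"}
        assert sorensen(a, b) == sorensen(b, a)
        with pytest.raises(ValueError):
            sorensen(set(), set())

    def test_sqrt_correlation_identity_and_scaling(self):
        v = [1.0, 4.0, 9.0, 2.0, 7.0]
        assert sqrt_abundance_correlation(v, v) == pytest.approx(1.0)
        assert sqrt_abundance_correlation(v, [4 * x for x in v]) == pytest.approx(1.0)

    def test_sqrt_correlation_matches_formula_oracle(self, rng):
        a = rng.integers(0, 50, 5).astype(float)
        b = rng.integers(0, 50, 5).astype(float)
        x, y = np.sqrt(a), np.sqrt(b)
        oracle = float(np.corrcoef(x, y)[0, 1])
        assert sqrt_abundance_correlation(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_sqrt_correlation_zero_variance_is_missing(self):
        assert math.isnan(sqrt_abundance_correlation([4.0, 4.0, 4.0], [1.0, 2.0, 3.0]))


def toy_matrix(abundances, coords=None):
    ab = np.asarray(abundances, dtype=float)
    n = ab.shape[0]
    if coords is None:
        coords = np.column_stack([np.linspace(0, 100, n), np.zeros(n)])
    return SiteBySpeciesMatrix(
        site_ids=tuple(f"s{i}" for i in range(n)),
        coords=np.asarray(coords, dtype=float),
        abundances=ab,
        species=tuple(f"sp{j}" for j in range(ab.shape[1])),
    )


class TestDistanceDecay:
    def test_identical_composition_gives_constant_unit_similarity(self):
        m = toy_matrix(np.tile([1.0, 2.0, 0.0, 5.0], (5, 1)))
        curve = distance_decay_curve(m, metric="sorensen", bins=3)
        vals = curve.mean_proficiency[~np.isnan(curve.mean_proficiency)]
        assert np.allclose(vals, 1.0)

    def test_two_sites_give_single_point_at_their_distance(self):
        m = toy_matrix([[1.0, 0.0], [1.0, 1.0]], coords=[[0, 0], [30, 40]])
        curve = distance_decay_curve(m, metric="sorensen", bins=1)
        assert len(curve) == 1
        assert curve.distances[0] == pytest.approx(50.0)  # bin midpoint = pair distance

    def test_bin_means_match_pair_enumeration_oracle(self, rng):
        ab = rng.integers(0, 4, size=(20, 10)).astype(float)
        m = toy_matrix(ab, coords=rng.uniform(0, 100, size=(20, 2)))
        curve = distance_decay_curve(m, metric="sorensen", bins=5)
        D = m.pairwise_distances_km()
        edges = np.linspace(0, 0, 0)
        # recompute with an explicit double loop
        pairs = []
        for i in range(20):
            for j in range(i + 1, 20):
                pi = {k for k in range(10) if ab[i, k] > 0}
                pj = {k for k in range(10) if ab[j, k] > 0}
                pairs.append((D[i, j], sorensen(pi, pj)))
        dists = np.array([p[0] for p in pairs])
        sims = np.array([p[1] for p in pairs])
        edges = np.linspace(dists.min(), dists.max(), 6)
        idx = np.clip(np.digitize(dists, edges) - 1, 0, 4)
        for b in range(5):
            expect = sims[idx == b].mean() if np.any(idx == b) else math.nan
            got = curve.mean_proficiency[b]
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_haversine_for_lonlat_coordinates(self):
        m = SiteBySpeciesMatrix(
            site_ids=("a", "b"), coords=np.array([[0.0, 0.0], [0.0, 1.0]]),
            abundances=np.ones((2, 3)), species=("x", "y", "z"), lonlat=True,
        )
        D = m.pairwise_distances_km()
        assert D[0, 1] == pytest.approx(111.19, abs=0.5)  # one degree of latitude


class TestPatristic:
    def test_two_tip_path_sum(self):
        tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        pdm = patristic_distances(tree)
        assert pdm.loc["A", "B"] == pytest.approx(3.0)

    def test_symmetric_with_zero_diagonal(self):
        tree = gen_yule_tree(10, 0.1, seed=4)
        pdm = patristic_distances(tree).to_numpy()
        assert np.allclose(pdm, pdm.T)
        assert np.allclose(np.diag(pdm), 0.0)

    def test_matches_bfs_path_sum_oracle_on_random_tree(self):
        tree = gen_yule_tree(8, 0.2, seed=5)
        pdm = patristic_distances(tree)
        oracle = bfs_patristic(tree)
        for a in pdm.index:
            for b in pdm.columns:
                assert pdm.loc[a, b] == pytest.approx(oracle[(a, b)], abs=1e-9)

    def test_missing_branch_lengths_rejected(self):
        tree = dendropy.Tree.get(data="(A,B);", schema="newick")
        with pytest.raises(ValueError, match="branch length"):
            patristic_distances(tree)


def synthetic_records(beta0, beta_b, beta_d, n, seed):
    rng = np.random.default_rng(seed)
    breadth = 1 + rng.poisson(2.0, n)
    dist = rng.exponential(50.0, n)
    eta = beta0 + beta_b * breadth + beta_d * dist
    used = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return [
        HostUseRecord(f"h{i%40}", f"p{i}", int(used[i]), int(breadth[i]), float(dist[i]))
        for i in range(n)
    ]


class TestHostUseModel:
    def test_parameter_recovery_within_three_standard_errors(self):
        recs = synthetic_records(0.0, 0.5, -0.02, 5000, seed=21)
        m = fit_host_use_model(recs)
        assert m.converged
        for est, se, truth in [
            (m.intercept, m.se[0], 0.0),
            (m.beta_breadth, m.se[1], 0.5),
            (m.beta_distance, m.se[2], -0.02),
        ]:
            assert abs(est - truth) < 3 * se

    def test_null_data_gives_null_coefficients(self):
        rng = np.random.default_rng(8)
        recs = [
            HostUseRecord(f"h{i%40}", f"p{i}", int(rng.random() < 0.3),
                          int(1 + rng.poisson(2.0)), float(rng.exponential(50.0)))
            for i in range(5000)
        ]
        m = fit_host_use_model(recs)
        assert abs(m.beta_breadth) < 3 * m.se[1]
        assert abs(m.beta_distance) < 3 * m.se[2]

    def test_single_class_outcome_rejected(self):
        recs = [HostUseRecord(f"h{i}", f"p{i}", 1, 2, float(i)) for i in range(20)]
        with pytest.raises(ValueError, match="both outcome classes"):
            fit_host_use_model(recs)

    def test_predictions_are_inverse_logit_of_linear_predictor(self):
        recs = synthetic_records(0.0, 0.5, -0.02, 200, seed=9)
        m = fit_host_use_model(recs)
        p = predict_host_use(m, recs[:1])
        r = recs[0]
        eta = m.intercept + m.beta_breadth * r.breadth + m.beta_distance * r.distance
        assert p[0] == pytest.approx(1.0 / (1.0 + math.exp(-eta)), abs=1e-12)

    def test_zero_coefficient_model_predicts_half(self):
        from ecohorizon.dimensional import HostUseModel

        m = HostUseModel(0.0, 0.0, 0.0, (0.0,) * 3, True)
        recs = synthetic_records(0.0, 0.5, -0.02, 10, seed=10)
        assert np.allclose(predict_host_use(m, recs), 0.5)


class TestAUC:
    def test_perfect_separation_and_all_ties(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_pair_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        wins = 0.0
        for sp in (0.35, 0.8):
            for sn in (0.1, 0.4):
                wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert auc(scores, labels) == pytest.approx(wins / 4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.random(30)
        labels = r.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        base = auc(scores, labels)
        assert auc(np.exp(3 * scores), labels) == pytest.approx(base, abs=1e-12)


class TestSliceCurve:
    def test_degenerate_distance_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            slice_proficiency_curve([0.5] * 20, [0, 1] * 10, [3.0] * 20)

    def test_counts_partition_records(self):
        rng = np.random.default_rng(11)
        n = 600
        d = rng.exponential(30.0, n)
        p = rng.random(n)
        y = rng.integers(0, 2, n)
        sc = slice_proficiency_curve(p, y, d, n_slices=6)
        assert sc.counts.sum() == n

    def test_pipeline_deterministic_from_seed(self):
        spec = PhyloFixtureSpec(n_plant_taxa=20, n_herbivores=15, seed=14)
        tree = gen_yule_tree(20, 0.1, seed=14)
        recs = gen_host_use_table(spec, tree)
        m = fit_host_use_model(recs)
        p = predict_host_use(m, recs)
        y = [r.used for r in recs]
        d = [r.distance for r in recs]
        a = slice_proficiency_curve(p, y, d, n_slices=6)
        b = slice_proficiency_curve(p, y, d, n_slices=6)
        assert np.array_equal(a.auc, b.auc, equal_nan=True)
        assert np.array_equal(a.midpoints, b.midpoints)
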