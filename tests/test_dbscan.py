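"""Density clustering: literal-definition oracle equivalence and geometry."""

import json

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import crashspat as cs
from crashspat.dbscan import (BORDER, CORE, NOISE_CLASS, cluster_hulls,
                              write_hulls, write_labels)

from _oracles import assert_equivalent, brute_dbscan, rand_index


def test_params_validation():
    with pytest.raises(ValueError):
        cs.DBSCANParams(0.0, 5)
    with pytest.raises(ValueError):
        cs.DBSCANParams(1.0, 0)


class TestEpsNeighborhood:
    def test_isolated_point_contains_itself(self):
        pts = cs.PointSet(np.array([[0.0, 0.0], [100.0, 100.0]]))
        assert list(cs.eps_neighborhood(pts, 0, 1.0)) == [0]

    def test_exactly_eps_apart_excluded(self):
        # strict inequality: d(p, q) < eps
        pts = cs.PointSet(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert list(cs.eps_neighborhood(pts, 0, 1.0)) == [0]
        assert list(cs.eps_neighborhood(pts, 1, 1.0)) == [1]
        assert set(cs.eps_neighborhood(pts, 0, 1.0 + 1e-9)) == {0, 1}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.random((200, 2))
        pts = cs.PointSet(coords)
        from _oracles import brute_neighborhoods
        oracle = brute_neighborhoods(coords, 0.1)
        for i in range(len(pts)):
            assert set(cs.eps_neighborhood(pts, i, 0.1)) == oracle[i]


class TestClassify:
    def test_single_point(self):
        pts = cs.PointSet(np.array([[0.0, 0.0]]))
        assert cs.classify_points(pts, cs.DBSCANParams(1.0, 2))[0] == NOISE_CLASS
        # self-membership alone suffices when min_pts = 1
        assert cs.classify_points(pts, cs.DBSCANParams(1.0, 1))[0] == CORE

    def test_matches_literal_definition(self, two_disc_points):
        points, _ = two_disc_points
        params = cs.DBSCANParams(50.0, 5)
        got = cs.classify_points(points, params)
        is_core, clusters = brute_dbscan(points.coords, 50.0, 5)
        covered = set().union(*clusters) if clusters else set()
        for i in range(len(points)):
            if is_core[i]:
                expect = CORE
            elif i in covered:
                expect = BORDER
            else:
                expect = NOISE_CLASS
            assert got[i] == expect


class TestDbscan:
    def test_two_planted_discs_recovered(self, two_disc_points):
        points, truth = two_disc_points
        res = cs.dbscan(points, cs.DBSCANParams(50.0, 5))
        assert res.n_clusters == 2
        planted = truth.true_cluster >= 0
        agreement = rand_index(truth.true_cluster[planted],
                               res.cluster_id[planted])
        assert agreement >= 0.95

    def test_all_coincident_points_one_cluster(self):
        pts = cs.PointSet(np.zeros((10, 2)), ids=np.arange(10))
        res = cs.dbscan(pts, cs.DBSCANParams(1.0, 10))
        assert res.n_clusters == 1
        assert len(res.clusters[0]) == 10

    def test_empty_pointset(self):
        res = cs.dbscan(cs.PointSet(np.empty((0, 2))), cs.DBSCANParams(1.0, 3))
        assert res.n_clusters == 0 and len(res.cluster_id) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        coords = rng.random((n, 2)) * 10
        eps = float(rng.uniform(0.2, 1.5))
        min_pts = int(rng.integers(2, 10))
        res = cs.dbscan(cs.PointSet(coords), cs.DBSCANParams(eps, min_pts))
        assert_equivalent(res, coords, eps, min_pts)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_grid_path_matches_bruteforce_path(self, seed):
        # above the grid threshold the spatial index must change nothing
        rng = np.random.default_rng(seed)
        coords = rng.random((1200, 2)) * 20
        res = cs.dbscan(cs.PointSet(coords), cs.DBSCANParams(0.5, 5))
        assert_equivalent(res, coords, 0.5, 5)

    def test_sklearn_core_agreement(self):
        # independent reference implementation; core partition must agree
        from sklearn.cluster import DBSCAN as SkDBSCAN
        rng = np.random.default_rng(10)
        coords = rng.random((300, 2))
        eps, min_pts = 0.08, 4
        res = cs.dbscan(cs.PointSet(coords), cs.DBSCANParams(eps, min_pts))
        # sklearn uses d <= eps; random continuous coords make ties
        # a measure-zero event, so results coincide
        sk = SkDBSCAN(eps=eps, min_samples=min_pts).fit(coords)
        sk_core = np.zeros(len(coords), bool)
        sk_core[sk.core_sample_indices_] = True
        assert np.array_equal(res.point_class == CORE, sk_core)
        # same core partition up to relabeling
        for members in res.clusters:
            cores = [m for m in members if sk_core[m]]
            assert len(set(sk.labels_[cores])) == 1

    def test_order_invariance_of_core_partition(self):
        rng = np.random.default_rng(2)
        coords = rng.random((150, 2))
        params = cs.DBSCANParams(0.1, 4)
        res_a = cs.dbscan(cs.PointSet(coords), params)
        perm = rng.permutation(len(coords))
        res_b = cs.dbscan(cs.PointSet(coords[perm]), params)
        core_a = res_a.point_class == CORE
        assert np.array_equal(core_a[perm], res_b.point_class == CORE)
        # partition restricted to cores invariant up to relabeling
        for members in res_a.clusters:
            cores = [m for m in members if core_a[m]]
            pos = [int(np.flatnonzero(perm == c)[0]) for c in cores]
            assert len(set(res_b.cluster_id[pos])) == 1

    def test_members_density_reachable_from_cluster_core(self):
        # replay the reachability definitions on a small instance
        rng = np.random.default_rng(5)
        coords = rng.random((80, 2))
        eps, min_pts = 0.15, 4
        res = cs.dbscan(cs.PointSet(coords), cs.DBSCANParams(eps, min_pts))
        from _oracles import brute_neighborhoods
        nbrs = brute_neighborhoods(coords, eps)
        is_core = res.point_class == CORE
        for members in res.clusters:
            members = set(int(m) for m in members)
            cores = {m for m in members if is_core[m]}
            # transitive closure of direct density-reachability from cores
            reach = set(cores)
            frontier = set(cores)
            while frontier:
                nxt = set()
                for c in frontier:
                    nxt |= nbrs[c] - reach
                reach |= nxt
                frontier = {q for q in nxt if is_core[q]}
            assert members <= reach


class TestSweep:
    def test_degenerate_grid_equals_direct_call(self, two_disc_points):
        points, _ = two_disc_points
        sweep = cs.sensitivity_sweep(points, [50.0], [5])
        direct = cs.dbscan(points, cs.DBSCANParams(50.0, 5))
        assert len(sweep) == 1
        assert sweep.loc[0, "n_clusters"] == direct.n_clusters
        assert sweep.loc[0, "n_core"] == direct.core_count

    def test_three_by_three_grid(self, two_disc_points):
        points, _ = two_disc_points
        sweep = cs.sensitivity_sweep(points, [20.0, 50.0, 80.0], [5, 10, 15])
        assert len(sweep) == 9

    def test_core_count_monotonicity(self, two_disc_points):
        points, _ = two_disc_points
        sweep = cs.sensitivity_sweep(points, [20.0, 50.0, 80.0], [3, 6, 12])
        for eps, grp in sweep.groupby("eps"):
            cores = grp.sort_values("min_pts")["n_core"].to_numpy()
            assert np.all(np.diff(cores) <= 0)
        for mp, grp in sweep.groupby("min_pts"):
            cores = grp.sort_values("eps")["n_core"].to_numpy()
            assert np.all(np.diff(cores) >= 0)


class TestHulls:
    def test_triangle(self):
        pts = cs.PointSet(np.array([[0, 0], [1, 0], [0, 1]], float))
        res = cs.dbscan(pts, cs.DBSCANParams(2.0, 3))
        (hull,) = cluster_hulls(pts, res)
        assert not hull.degenerate
        assert hull.area == pytest.approx(0.5)

    def test_square_with_interior_point(self):
        pts = cs.PointSet(np.array([[0, 0], [1, 0], [1, 1], [0, 1],
                                    [0.5, 0.5]], float))
        res = cs.dbscan(pts, cs.DBSCANParams(3.0, 5))
        (hull,) = cluster_hulls(pts, res)
        assert hull.area == pytest.approx(1.0)
        assert len(hull.geometry.exterior.coords) - 1 == 4

    def test_matches_independent_hull(self, two_disc_points):
        points, _ = two_disc_points
        res = cs.dbscan(points, cs.DBSCANParams(50.0, 5))
        for hull in cluster_hulls(points, res):
            members = res.clusters[hull.cluster_id]
            expect = ConvexHull(points.coords[members]).volume  # 2-D area
            assert hull.area == pytest.approx(expect)

    def test_degenerate_two_point_cluster_flagged(self):
        pts = cs.PointSet(np.array([[0, 0], [0.1, 0]], float))
        res = cs.dbscan(pts, cs.DBSCANParams(1.0, 2))
        (hull,) = cluster_hulls(pts, res)
        assert hull.degenerate and hull.area == 0.0

    def test_geojson_export(self, two_disc_points, tmp_path):
        points, _ = two_disc_points
        res = cs.dbscan(points, cs.DBSCANParams(50.0, 5))
        hulls = cluster_hulls(points, res)
        path = tmp_path / "hulls.geojson"
        write_hulls(hulls, path)
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == res.n_clusters
        props = doc["features"][0]["properties"]
        assert {"cluster_id", "member_count", "core_count"} <= props.keys()


def test_label_file_roundtrip(two_disc_points, tmp_path):
    import pandas as pd
    points, _ = two_disc_points
    res = cs.dbscan(points, cs.DBSCANParams(50.0, 5))
    path = tmp_path / "labels.csv"
    write_labels(points, res, path)
    df = pd.read_csv(path)
    assert np.array_equal(df["cluster_id"].to_numpy(), res.cluster_id)
    assert list(df.columns) == ["id", "x", "y", "point_class", "cluster_id"]
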