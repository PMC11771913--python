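"""Independent brute-force oracles used only by the tests.

These evaluate the density-clustering definitions literally and
inefficiently, with no code shared with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_neighborhoods(coords: np.ndarray, eps: float) -> list[set]:
    """Strict eps-neighbourhood of every point, by exhaustive pairwise scan."""
    n = len(coords)
    out = []
    for i in range(n):
        nb = {j for j in range(n)
              if np.hypot(*(coords[i] - coords[j])) < eps}
        out.append(nb)
    return out


def brute_dbscan(coords: np.ndarray, eps: float, min_pts: int):
    """Literal evaluation of the density-clustering definitions.

    Returns (is_core, clusters) where clusters is a list of frozensets:
    each cluster is the set of core points of one connected component of
    the core-proximity graph, plus every non-core point lying in some
    component core's eps-neighbourhood.  Border points reachable from two
    components appear in both returned sets (tie unresolved — the oracle
    reports all legal assignments).
    """
    n = len(coords)
    nbrs = brute_neighborhoods(coords, eps)
    is_core = np.array([len(nbrs[i]) >= min_pts for i in range(n)])

    # connected components of core points under direct density-reachability
    comp = {}
    for i in range(n):
        if not is_core[i] or i in comp:
            continue
        stack, cid = [i], len(set(comp.values()))
        comp[i] = cid
        while stack:
            p = stack.pop()
            for q in nbrs[p]:
                if is_core[q] and q not in comp:
                    comp[q] = cid
                    stack.append(q)
    n_comp = len(set(comp.values()))
    clusters = []
    for cid in range(n_comp):
        cores = {i for i, c in comp.items() if c == cid}
        members = set(cores)
        for q in range(n):
            if not is_core[q] and any(q in nbrs[c] for c in cores):
                members.add(q)
        clusters.append(frozenset(members))
    return is_core, clusters


def assert_equivalent(result, coords: np.ndarray, eps: float,
                      min_pts: int) -> None:
    """Implementation output must match the literal definitions.

    Core labels exactly; the partition restricted to cores up to
    relabeling; every border point assigned to one of the clusters that
    legally reach it; noise exactly the points in no oracle cluster.
    """
    is_core, oracle_clusters = brute_dbscan(coords, eps, min_pts)
    impl_core = result.point_class == "core"
    assert np.array_equal(impl_core, is_core), "core labels differ"

    assert result.n_clusters == len(oracle_clusters), (
        f"{result.n_clusters} clusters vs oracle {len(oracle_clusters)}")

    # map each impl cluster to the unique oracle cluster sharing its cores
    for members in result.clusters:
        members = set(int(m) for m in members)
        cores = {m for m in members if is_core[m]}
        assert cores, "cluster without a core point"
        matches = [oc for oc in oracle_clusters if cores <= oc]
        assert len(matches) == 1, "cluster cores split across oracle clusters"
        oracle = matches[0]
        oracle_cores = {m for m in oracle if is_core[m]}
        assert cores == oracle_cores, "core partition differs"
        for m in members - cores:     # border members must be legal
            assert m in oracle, f"border point {m} not reachable from cluster"

    covered = set().union(*oracle_clusters) if oracle_clusters else set()
    impl_noise = {i for i in range(len(coords))
                  if result.cluster_id[i] == -1}
    assert impl_noise == set(range(len(coords))) - covered, "noise set differs"


def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Rand index between two label vectors (pair counting)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / (n * (n - 1) / 2)
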