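"""L1 distances, deterministic complete linkage, tree queries, Newick export."""

import io
import itertools

import numpy as np
import pytest
from Bio import Phylo
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from tssr import (
    DistanceMatrix,
    ProfileTable,
    TSSRVector,
    cityblock_distances,
    complete_linkage,
    is_monophyletic,
    linkage_tree,
    smallest_containing_cluster,
    to_newick,
)


def _table(rows):
    vecs = tuple(TSSRVector(tuple(r)) for r in rows)
    ids = tuple(f"g{i}" for i in range(len(rows)))
    return ProfileTable(ids, (None,) * len(rows), vecs)


def brute_force_complete_heights(dm: np.ndarray) -> list[float]:
    """Oracle: recompute max pairwise member distances from scratch each merge."""
    clusters = [frozenset([i]) for i in range(len(dm))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(dm[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestCityblock:
    def test_identical_rows_zero(self):
        t = _table([[1 / 9] * 9, [1 / 9] * 9])
        assert cityblock_distances(t).values[0, 1] == 0

    def test_simplex_corners(self):
        t = _table([[1] + [0] * 8, [0, 1] + [0] * 7])
        assert cityblock_distances(t).values[0, 1] == pytest.approx(2.0)

    def test_typhus_pair_from_printed_cells(self, table61):
        """Hand L1 oracle over the 9 printed cells of the two typhus genomes:
        sum(|delta|) = 0.008 raw, 0.0085 after row renormalisation."""
        d = cityblock_distances(table61)
        got = d.get(
            "Rickettsia prowazekii str. Madrid E", "Rickettsia typhi str. Wilmington"
        )
        prow = (0.009, 0.002, 0.002, 0.204, 0.163, 0.059, 0.283, 0.086, 0.193)
        typh = (0.008, 0.002, 0.002, 0.202, 0.161, 0.059, 0.284, 0.086, 0.195)
        pn = np.array(prow) / sum(prow)
        tn = np.array(typh) / sum(typh)
        assert got == pytest.approx(float(np.abs(pn - tn).sum()), abs=1e-9)
        assert got == pytest.approx(0.0085, abs=5e-4)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            cityblock_distances(_table([[1 / 9] * 9]))

    def test_triangle_inequality_on_random_profiles(self, rng):
        X = rng.dirichlet(np.ones(9), size=12)
        t = _table(X.tolist())
        v = cityblock_distances(t).values
        for i, j, k in itertools.permutations(range(12), 3):
            assert v[i, k] <= v[i, j] + v[j, k] + 1e-12


def _dm(labels, pairs):
    n = len(labels)
    m = np.zeros((n, n))
    for (i, j), v in pairs.items():
        m[i, j] = m[j, i] = v
    return DistanceMatrix(tuple(labels), m)


class TestCompleteLinkage:
    def test_three_point_merge_order(self):
        d = _dm("ABC", {(0, 1): 1.0, (0, 2): 5.0, (1, 2): 4.0})
        t = complete_linkage(d)
        assert t.merge_heights == (1.0, 5.0)
        assert smallest_containing_cluster(t, ["A", "B"]).leaves == {"A", "B"}

    def test_identical_points_merge_at_zero(self):
        t = _table([[1 / 9] * 9] * 5)
        tree = complete_linkage(cityblock_distances(t))
        assert tree.merge_heights == (0.0,) * 4

    def test_heights_monotone(self, table61):
        tree = complete_linkage(cityblock_distances(table61))

        def check(node):
            if node.is_leaf:
                return
            for child in (node.left, node.right):
                assert child.height <= node.height + 1e-12
                check(child)

        check(tree.root)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_brute_force_oracle(self, n, rng):
        for _ in range(10):
            m = rng.random((n, n))
            m = np.triu(m, 1)
            m = m + m.T
            d = DistanceMatrix(tuple(str(i) for i in range(n)), m)
            got = complete_linkage(d).merge_heights
            assert np.allclose(got, brute_force_complete_heights(m), atol=1e-12)

    @pytest.mark.parametrize("method", ["complete", "single", "average"])
    def test_matches_scipy_heights(self, method, rng):
        """Independent library cross-check on continuous (tie-free) distances."""
        X = rng.random((10, 9))
        t = _table((X / X.sum(axis=1, keepdims=True)).tolist())
        d = cityblock_distances(t)
        ours = linkage_tree(d, method=method).merge_heights
        Z = scipy_linkage(squareform(d.values, checks=False), method=method)
        assert np.allclose(sorted(ours), sorted(Z[:, 2]), atol=1e-10)

    def test_row_order_invariance(self, table61, rng):
        base = complete_linkage(cityblock_distances(table61))
        groups = {
            sub: [g for g, s in zip(table61.genome_ids, table61.subphyla) if s == sub]
            for sub in ("alpha", "beta", "gamma")
        }
        for _ in range(20):
            perm = rng.permutation(len(table61))
            t = ProfileTable(
                tuple(table61.genome_ids[i] for i in perm),
                tuple(table61.subphyla[i] for i in perm),
                tuple(table61.vectors[i] for i in perm),
            )
            tree = complete_linkage(cityblock_distances(t))
            assert np.allclose(tree.merge_heights, base.merge_heights, atol=1e-12)
            for sub, members in groups.items():
                assert is_monophyletic(tree, members) == is_monophyletic(base, members)


@pytest.fixture(scope="module")
def tree61(table61):
    return complete_linkage(cityblock_distances(table61))


class TestTreeQueries:

    def test_full_query_returns_root(self, tree61, table61):
        node = smallest_containing_cluster(tree61, table61.genome_ids)
        assert node is tree61.root

    def test_single_leaf(self, tree61):
        node = smallest_containing_cluster(tree61, ["Yersinia pestis KIM"])
        assert node.is_leaf and len(node.leaves) == 1

    def test_unknown_label_raises(self, tree61):
        with pytest.raises(KeyError):
            smallest_containing_cluster(tree61, ["no such genome"])

    def test_escherichia_shigella_cluster_has_28_leaves(self, tree61, table61):
        query = [
            g for g in table61.genome_ids if g.startswith(("Escherichia", "Shigella"))
        ]
        assert len(query) == 28
        assert len(smallest_containing_cluster(tree61, query).leaves) == 28

    def test_rickettsia_cluster_has_11_leaves(self, tree61, table61):
        query = [g for g in table61.genome_ids if g.startswith("Rickettsia")]
        assert len(query) == 11
        assert len(smallest_containing_cluster(tree61, query).leaves) == 11

    def test_subphyla_monophyletic(self, tree61, table61):
        for sub in ("alpha", "beta", "gamma"):
            members = [
                g for g, s in zip(table61.genome_ids, table61.subphyla) if s == sub
            ]
            assert is_monophyletic(tree61, members)

    def test_singleton_and_full_groups_monophyletic(self, tree61, table61):
        assert is_monophyletic(tree61, [table61.genome_ids[0]])
        assert is_monophyletic(tree61, table61.genome_ids)


class TestNewick:
    def test_two_leaves_midpoint_convention(self):
        d = _dm("AB", {(0, 1): 0.4})
        assert to_newick(complete_linkage(d)) == "(A:0.2,B:0.2);"

    def test_unit_scale_root_height(self):
        d = _dm("ABC", {(0, 1): 1.0, (0, 2): 5.0, (1, 2): 4.0})
        t = complete_linkage(d)
        text = to_newick(t, scale="unit")
        tree = Phylo.read(io.StringIO(text), "newick")
        depths = tree.depths()
        assert max(depths.values()) == pytest.approx(0.5)  # root height 1, halved

    def test_round_trip_topology(self, table61):
        tree = complete_linkage(cityblock_distances(table61))
        text = to_newick(tree)
        parsed = Phylo.read(io.StringIO(text), "newick")
        parsed_clades = {
            frozenset(l.name for l in c.get_terminals())
            for c in parsed.get_nonterminals()
        }
        from tssr.cluster import newick_safe

        ours = {
            frozenset(newick_safe(l) for l in n.leaves)
            for n in tree.root
            if not n.is_leaf
        }
        assert parsed_clades == ours
        assert len(parsed.get_terminals()) == 61
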