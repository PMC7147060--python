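import io

import numpy as np
import pytest

from quartetbm.distances import is_additive
from quartetbm.io import (read_color_map, read_newick, read_phylip_square,
                          write_color_map, write_newick, write_phylip_square)
from quartetbm.trees import PlantedTree

from conftest import random_length_tree


def brute_force_lca(tree, labels):
    """Oracle: intersect root paths, take the deepest shared vertex."""
    depths = tree.depths()
    paths = []
    for lab in labels:
        node, path = tree.find_leaf(lab), set()
        while node is not None:
            path.add(node.id)
            node = node.parent
        paths.append(path)
    common = set.intersection(*paths)
    return max(common, key=lambda i: depths[i])


class TestLca:
    def test_singleton_is_identity(self):
        t = PlantedTree.from_nested([["a", "b"], "c"])
        assert t.lca(["a"]).label == "a"

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(10):
            t = random_length_tree(12, rng)
            labels = t.leaf_labels()
            for _ in range(15):
                k = int(rng.integers(2, 5))
                subset = list(rng.choice(labels, size=k, replace=False))
                assert t.lca(subset).id == brute_force_lca(t, subset)

    def test_associative_over_union(self, rng):
        # lca(A u B) has the same depth as lca({lca(A), lca(B)})
        for _ in range(5):
            t = random_length_tree(10, rng)
            labels = t.leaf_labels()
            a = list(rng.choice(labels, size=3, replace=False))
            b = list(rng.choice(labels, size=3, replace=False))
            joint = t.lca(a + b)
            la, lb = t.lca(a), t.lca(b)
            # walk up from the deeper of la, lb until both are covered
            assert brute_force_lca(t, a + b) == joint.id

    def test_total_order_along_focal_leaf(self, rng):
        # the lcas of a fixed leaf with all others lie on its root path
        for _ in range(5):
            t = random_length_tree(10, rng)
            labels = t.leaf_labels()
            x = labels[0]
            node, root_path = t.find_leaf(x), set()
            while node is not None:
                root_path.add(node.id)
                node = node.parent
            for y in labels[1:]:
                assert t.lca([x, y]).id in root_path

    def test_unknown_label_raises(self):
        t = PlantedTree.from_nested(["a", "b"])
        with pytest.raises(KeyError):
            t.lca(["a", "nope"])


class TestRestrict:
    def test_full_leaf_set_is_identity(self, rng):
        t = random_length_tree(8, rng)
        r = t.restrict(t.leaf_labels())
        assert sorted(r.leaf_labels()) == sorted(t.leaf_labels())
        d0, d1 = t.path_distance_matrix(), r.path_distance_matrix()
        labs = sorted(t.leaf_labels())
        assert np.allclose(d0.submatrix(labs).data, d1.submatrix(labs).data)

    def test_caterpillar_pair_preserves_distance(self):
        # caterpillar (((a,b),c),d); keep {a, d}
        t = PlantedTree.from_nested(
            [([([("a", 1.0), ("b", 1.0)], 2.0), ("c", 1.0)], 3.0), ("d", 1.0)])
        full = t.path_distance_matrix()
        r = t.restrict(["a", "d"])
        assert sorted(r.leaf_labels()) == ["a", "d"]
        assert len(r.root.children) == 2
        assert all(c.is_leaf for c in r.root.children)
        assert r.path_distance_matrix()["a", "d"] == pytest.approx(
            full["a", "d"])

    def test_restrict_commutes_with_unroot(self, rng):
        for _ in range(5):
            t = random_length_tree(9, rng)
            keep = sorted(rng.choice(t.leaf_labels(), size=5, replace=False))
            a = t.restrict(keep).unroot()
            b = t.unroot()
            da = a.path_distance_matrix(keep)
            db = b.path_distance_matrix(keep)
            assert np.allclose(da.data, db.data)

    def test_empty_restriction_raises(self):
        t = PlantedTree.from_nested(["a", "b"])
        with pytest.raises(ValueError):
            t.restrict([])


class TestUnroot:
    def test_two_leaf_merge(self):
        t = PlantedTree.from_nested([("a", 0.3), ("b", 0.7)])
        u = t.unroot()
        assert u.graph.number_of_edges() == 1
        (_, _, data), = u.graph.edges(data=True)
        assert data["length"] == pytest.approx(1.0)

    def test_multifurcating_root_is_kept(self):
        t = PlantedTree.from_nested([("a", 1.0), ("b", 1.0), ("c", 1.0)])
        u = t.unroot()
        assert u.graph.number_of_nodes() == 4  # root vertex retained

    def test_distances_preserved(self, rng):
        t = random_length_tree(10, rng)
        labs = sorted(t.leaf_labels())
        assert np.allclose(t.path_distance_matrix(labs).data,
                           t.unroot().path_distance_matrix(labs).data)

    def test_single_leaf_raises(self):
        t = PlantedTree.from_nested("a")
        with pytest.raises(ValueError):
            t.unroot()


class TestPathDistances:
    def test_star_unit_edges(self):
        t = PlantedTree.from_nested([("a", 1.0), ("b", 1.0), ("c", 1.0)])
        d = t.path_distance_matrix()
        off = d.data[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 2.0)
        assert np.all(np.diag(d.data) == 0)

    def test_four_point_condition_holds(self, rng):
        for _ in range(5):
            t = random_length_tree(8, rng)
            assert is_additive(t.path_distance_matrix(), tol=1e-9)

    def test_missing_length_raises(self):
        t = PlantedTree.from_nested([["a", "b"], "c"])
        with pytest.raises(ValueError):
            t.path_distance_matrix()


class TestIO:
    def test_newick_round_trip(self, rng, tmp_path):
        for i in range(5):
            t = random_length_tree(7, rng)
            path = str(tmp_path / f"t{i}.nwk")
            write_newick(t, path)
            back = read_newick(path)
            labs = sorted(t.leaf_labels())
            assert sorted(back.leaf_labels()) == labs
            assert np.allclose(t.path_distance_matrix(labs).data,
                               back.path_distance_matrix(labs).data,
                               atol=1e-9)

    def test_newick_support_values_ignored(self):
        t = read_newick("((a:1,b:2)0.95:1,(c:1,d:1)0.80:2);", is_path=False)
        assert sorted(t.leaf_labels()) == ["a", "b", "c", "d"]

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError):
            read_newick("((a:1,b:2;", is_path=False)

    def test_phylip_round_trip(self, rng, tmp_path):
        t = random_length_tree(6, rng)
        d = t.path_distance_matrix()
        path = str(tmp_path / "d.phylip")
        write_phylip_square(d, path)
        back = read_phylip_square(path)
        assert back.labels == d.labels
        assert np.allclose(back.data, d.data, atol=1e-10)

    def test_phylip_malformed_reports_line(self):
        buf = io.StringIO("2\nA\t0.0\t1.0\nB\t1.0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_phylip_square(buf)

    def test_color_map_round_trip(self, tmp_path):
        color = {"g1": "s1", "g2": "s2"}
        path = str(tmp_path / "c.tsv")
        write_color_map(color, path)
        assert read_color_map(path) == color
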