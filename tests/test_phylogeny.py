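import numpy as np
import pytest

from wrkyfam import phylogeny as ph
from wrkyfam.phylogeny import (
    DistanceMatrix,
    NewickError,
    Tree,
    TreeNode,
    leaf_path_lengths,
    nj_tree,
    pairwise_distance,
    parse_newick,
    same_topology,
    to_newick,
)


def random_additive_tree(n, rng):
    """Random unrooted binary tree with positive branch lengths and the
    exactly additive distance matrix it induces."""
    leaves = [f"t{i:02d}" for i in range(n)]
    root = TreeNode(children=[TreeNode(name=l) for l in leaves[:3]])
    for c in root.children:
        c.length = rng.uniform(0.05, 1.0)

    def edges(node):
        out = []
        for c in node.children:
            out.append((node, c))
            out.extend(edges(c))
        return out

    for name in leaves[3:]:
        parent, child = edges(root)[rng.integers(len(edges(root)))]
        mid = TreeNode()
        leaf = TreeNode(name=name, length=rng.uniform(0.05, 1.0))
        split = rng.uniform(0.2, 0.8)
        mid.length = child.length * split
        child.length = child.length * (1 - split)
        mid.children = [child, leaf]
        parent.children[parent.children.index(child)] = mid

    tree = Tree(root)
    pl = leaf_path_lengths(tree)
    d = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j in range(i + 1, n):
            b = leaves[j]
            d[i, j] = d[j, i] = pl[(a, b) if a < b else (b, a)]
    return tree, DistanceMatrix(leaves, d)


class TestPairwiseDistance:
    def test_identical_sequences_are_zero(self):
        assert pairwise_distance("MKVRRA", "MKVRRA") == 0.0

    def test_one_mismatch_in_four(self):
        assert pairwise_distance("AAAA", "AAAT") == pytest.approx(0.25)

    def test_symmetry_on_random_pairs(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(5, 40))))
            assert pairwise_distance(a, b) == pytest.approx(
                pairwise_distance(b, a)
            )

    def test_bounded_in_unit_interval(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(alphabet, size=20))
            b = "".join(rng.choice(alphabet, size=25))
            assert 0.0 <= pairwise_distance(a, b) <= 1.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {n.name: n.length for n in t.root.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_five_leaf_additive_topology_recovered(self):
        rng = np.random.default_rng(5)
        truth, dm = random_additive_tree(5, rng)
        assert same_topology(truth, nj_tree(dm))

    def test_additive_consistency_over_seeded_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            truth, dm = random_additive_tree(n, rng)
            out = nj_tree(dm)
            assert same_topology(truth, out)
            # reconstructed path lengths reproduce the input distances
            pl = leaf_path_lengths(out)
            idx = {t: i for i, t in enumerate(dm.taxa)}
            err = max(
                abs(v - dm.d[idx[a], idx[b]]) for (a, b), v in pl.items()
            )
            assert err < 1e-9

    def test_six_leaf_matches_exhaustive_least_squares(self):
        # brute-force oracle: score every unrooted 6-leaf topology by
        # least-squares branch fit to the distances; NJ must find the best
        from itertools import combinations

        rng = np.random.default_rng(3)
        truth, dm = random_additive_tree(6, rng)
        leaves = dm.taxa

        def enumerate_topologies(names):
            # grow all topologies by inserting leaves on every edge
            base = Tree(TreeNode(children=[TreeNode(name=n) for n in names[:3]]))
            trees = [base]
            for name in names[3:]:
                nxt = []
                for t in trees:
                    s = to_newick(t)
                    # count edges by re-parsing to keep trees independent
                    for k in range(_n_edges(parse_newick(s))):
                        t2 = parse_newick(s)
                        _insert_on_edge(t2, k, name)
                        nxt.append(t2)
                trees = nxt
            return trees

        def _edges(tree):
            out = []

            def walk(node):
                for c in node.children:
                    out.append((node, c))
                    walk(c)

            walk(tree.root)
            return out

        def _n_edges(tree):
            return len(_edges(tree))

        def _insert_on_edge(tree, k, name):
            parent, child = _edges(tree)[k]
            mid = TreeNode(children=[child, TreeNode(name=name)])
            parent.children[parent.children.index(child)] = mid

        def ls_residual(tree):
            # path-edge incidence least squares on branch lengths
            edge_list = _edges(tree)
            eindex = {id(c): i for i, (_, c) in enumerate(edge_list)}
            rows, y = [], []

            def path_edges(node, acc, paths):
                if node.is_leaf:
                    paths[node.name] = list(acc)
                for c in node.children:
                    acc.append(id(c))
                    path_edges(c, acc, paths)
                    acc.pop()

            paths = {}
            path_edges(tree.root, [], paths)
            idx = {t: i for i, t in enumerate(leaves)}
            for a, b in combinations(leaves, 2):
                row = np.zeros(len(edge_list))
                for e in set(paths[a]) ^ set(paths[b]):
                    row[eindex[e]] = 1.0
                rows.append(row)
                y.append(dm.d[idx[a], idx[b]])
            A = np.array(rows)
            sol, res, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
            return float(((A @ sol - np.array(y)) ** 2).sum())

        topologies = enumerate_topologies(leaves)
        assert len(topologies) == 105
        best = min(topologies, key=ls_residual)
        assert same_topology(best, nj_tree(dm))

    def test_non_symmetric_matrix_rejected(self):
        d = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], d)

    def test_deterministic_output(self):
        rng = np.random.default_rng(8)
        _, dm = random_additive_tree(7, rng)
        assert to_newick(nj_tree(dm)) == to_newick(nj_tree(dm))


class TestNewick:
    def test_three_leaf_shape(self):
        t = nj_tree(DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)))
        s = to_newick(t)
        assert s.endswith(";")
        assert s.count("(") == s.count(")") == 1

    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            _, dm = random_additive_tree(int(rng.integers(4, 10)), rng)
            t = nj_tree(dm)
            t2 = parse_newick(to_newick(t))
            assert same_topology(t, t2)
            pl1, pl2 = leaf_path_lengths(t), leaf_path_lengths(t2)
            assert all(abs(pl1[k] - pl2[k]) < 1e-5 for k in pl1)

    def test_unbalanced_parentheses_error_reports_position(self):
        with pytest.raises(NewickError) as err:
            parse_newick("((a,b);")
        assert err.value.position >= 0

    def test_missing_semicolon(self):
        with pytest.raises(NewickError):
            parse_newick("(a,b)")


class TestAgainstIndependentImplementation:
    def test_topology_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(17)
        for _ in range(5):
            _, dm = random_additive_tree(int(rng.integers(5, 10)), rng)
            mine = nj_tree(dm)
            theirs = parse_newick(str(sknj(skbio.DistanceMatrix(dm.d, ids=dm.taxa))))
            assert same_topology(mine, theirs)
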