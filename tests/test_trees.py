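"""PCoA, BioNJ, MST and path-length residual diagnostics."""

import itertools

import dendropy
import numpy as np
import pytest

from arctos.trees import bionj, leaf_distance_matrix, mst, pcoa, tree_residuals


def random_additive_matrix(rng, n):
    """Distance matrix generated from a random binary tree with random lengths."""
    nodes = [dendropy.Node() for _ in range(n)]
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    for i, node in enumerate(nodes):
        node.taxon = taxa.get_taxon(f"t{i}")
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = float(rng.uniform(0.5, 2))
        parent.add_child(nodes[j]); nodes[j].edge.length = float(rng.uniform(0.5, 2))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
        node.edge.length = float(rng.uniform(0.5, 2))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    labels, dm = leaf_distance_matrix(tree)
    return tree, labels, dm


class TestPcoa:
    def test_points_on_a_line_recovered_on_first_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        dm = np.abs(np.subtract.outer(x, x))
        res = pcoa(dm)
        axis = res.coordinates[:, 0]
        spacing = np.diff(axis)
        assert np.allclose(np.abs(spacing), 1.0, atol=1e-9)

    def test_euclidean_matrix_reconstructs_distances(self, rng):
        pts = rng.normal(size=(7, 3))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(dm)
        rec = np.linalg.norm(res.coordinates[:, None] - res.coordinates[None, :], axis=2)
        assert np.allclose(rec, dm, atol=1e-9)

    def test_regular_simplex_has_equal_positive_eigenvalues(self):
        n = 5
        dm = np.ones((n, n)) - np.eye(n)
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == n - 1
        assert np.allclose(pos, pos[0])

    def test_eigenvalue_sum_equals_centered_trace(self, rng):
        pts = rng.normal(size=(6, 4))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(dm)
        n = dm.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dm**2) @ j
        assert np.sum(res.eigenvalues) == pytest.approx(np.trace(b))

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(8, 3))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        mine = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm))
        ev_theirs = np.sort(theirs.eigvals.to_numpy())[::-1]
        np.testing.assert_allclose(mine.eigenvalues[:3], ev_theirs[:3], atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0, 1], [2, 0]], dtype=float))


class TestBionj:
    def test_three_taxa_closed_form(self):
        dm = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = bionj(dm, ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(3.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(6.0)

    def test_additive_matrix_recovered_exactly(self, rng):
        for _ in range(5):
            _, labels, dm = random_additive_matrix(rng, 8)
            tree = bionj(dm, labels)
            labs, path = leaf_distance_matrix(tree)
            perm = [labs.index(l) for l in labels]
            np.testing.assert_allclose(path[np.ix_(perm, perm)], dm, atol=1e-9)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            bionj(np.zeros((2, 2)), ["a", "b"])

    def test_agrees_with_reference_nj_under_small_noise(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        agree = 0
        trials = 20
        for _ in range(trials):
            true_tree, labels, dm = random_additive_matrix(rng, 7)
            noisy = dm + rng.normal(scale=0.01, size=dm.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            mine = bionj(noisy, labels)
            theirs = skbio_nj(skbio.DistanceMatrix(noisy, ids=labels))
            t1 = mine
            tns = t1.taxon_namespace
            t2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                                   taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            agree += rf == 0
        assert agree / trials >= 0.95


class TestResiduals:
    def test_zero_on_additive_matrix(self, rng):
        _, labels, dm = random_additive_matrix(rng, 6)
        tree = bionj(dm, labels)
        res = tree_residuals(tree, dm, labels)
        assert np.allclose(res, 0, atol=1e-9)

    def test_symmetric(self, rng):
        _, labels, dm = random_additive_matrix(rng, 6)
        noisy = dm + rng.normal(scale=0.1, size=dm.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        tree = bionj(noisy, labels)
        res = tree_residuals(tree, noisy, labels)
        np.testing.assert_allclose(res, res.T)

    def test_tip_mismatch_raises(self, rng):
        _, labels, dm = random_additive_matrix(rng, 5)
        tree = bionj(dm, labels)
        with pytest.raises(ValueError):
            tree_residuals(tree, dm, ["x"] * 5)

    def test_admixed_sample_attracted_to_both_donors(self, rng):
        # Distance geometry of admixture: the hybrid is closer to both donor
        # clades than any tree can represent, so its residuals to them are
        # positive (path length exceeds observed distance: attraction).
        labels = ["d1", "d1b", "d2", "d2b", "hyb", "out"]
        base = {("d1", "d1b"): 0.02, ("d2", "d2b"): 0.02}
        dm = np.zeros((6, 6))
        coord = {"d1": 0.0, "d1b": 0.02, "d2": 1.0, "d2b": 1.02, "out": 3.0}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    continue
                if a == "hyb" or b == "hyb":
                    other = b if a == "hyb" else a
                    # hybrid midway: closer to both donors than additivity allows
                    dm[i, j] = 0.3 if other in ("d1", "d1b", "d2", "d2b") else 2.0
                else:
                    dm[i, j] = abs(coord[a] - coord[b])
        tree = bionj(dm, labels)
        res = tree_residuals(tree, dm, labels)
        h = labels.index("hyb")
        donors = [labels.index(x) for x in ("d1", "d1b", "d2", "d2b")]
        assert np.mean(res[h, donors]) > 0


class TestMst:
    def test_chain_distances_give_chain_tree(self):
        x = np.arange(5.0)
        dm = np.abs(np.subtract.outer(x, x))
        edges = mst(dm, [f"n{i}" for i in range(5)])
        assert sorted((a, b) for a, b, _ in edges) == [
            ("n0", "n1"), ("n1", "n2"), ("n2", "n3"), ("n3", "n4")]

    def test_deterministic_under_ties(self):
        dm = np.ones((4, 4)) - np.eye(4)
        e1 = mst(dm, ["a", "b", "c", "d"])
        e2 = mst(dm, ["a", "b", "c", "d"])
        assert e1 == e2
        assert [(a, b) for a, b, _ in e1] == [("a", "b"), ("a", "c"), ("a", "d")]

    def test_total_weight_matches_exhaustive_minimum(self, rng):
        n = 6
        dm = rng.random((n, n))
        dm = (dm + dm.T) / 2
        np.fill_diagonal(dm, 0)
        edges = mst(dm, [str(i) for i in range(n)])
        total = sum(w for _, _, w in edges)
        all_edges = list(itertools.combinations(range(n), 2))
        best = np.inf
        for combo in itertools.combinations(all_edges, n - 1):
            # connectivity check by union-find
            parent = list(range(n))
            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x
            ok = True
            for i, j in combo:
                ri, rj = find(i), find(j)
                if ri == rj:
                    ok = False
                    break
                parent[ri] = rj
            if ok:
                best = min(best, sum(dm[i, j] for i, j in combo))
        assert total == pytest.approx(best)
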