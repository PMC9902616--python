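"""Distance-based clustering: PCoA, BioNJ, minimum spanning tree, residuals.

BioNJ is the variance-weighted flavour of neighbour joining: at each
agglomeration the new distances to the joined pair are a convex combination
whose weight minimises the variance of the resulting distance estimates
(variances are initialised to the distances themselves and updated
alongside them).  On an additive (tree-like) matrix it recovers the
generating topology and branch lengths exactly, like plain NJ.

The path-length residual diagnostic compares, for every tip pair, the
patristic distance implied by a dendrogram with the entry of the distance
matrix it was built from; systematic non-zero residuals indicate non-treelike
structure such as admixture (a negative residual means the two samples are
more similar than the tree suggests: attraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, n_positive_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)


def pcoa(dm: np.ndarray, labels: list[str] | None = None) -> PCoAResult:
    """Principal coordinates analysis (Gower double-centering).

    Axes are ordered by eigenvalue; axes with non-positive eigenvalues are
    reported in ``eigenvalues`` but dropped from the coordinates.
    """
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    n = dm.shape[0]
    labels = labels or [str(i) for i in range(n)]
    d2 = dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    return PCoAResult(labels=list(labels), coordinates=coords, eigenvalues=evals)


def bionj(dm: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """BioNJ agglomeration of a symmetric distance matrix.

    Returns an unrooted :class:`dendropy.Tree` whose seed node is the final
    trifurcation.  Ties in the neighbour-joining criterion are broken by the
    lowest label-index pair, so the output is deterministic.
    """
    d = np.asarray(dm, dtype=float).copy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("bionj needs at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) != n:
        raise ValueError("one label per matrix row required")

    taxa = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    v = d.copy()  # variance estimates
    order = list(range(n))  # original index carried for tie-breaking

    while len(nodes) > 3:
        m = len(nodes)
        s = d.sum(axis=1)
        q = (m - 2) * d - s[:, None] - s[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest Q; ties resolved by the smallest (original-index) pair
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = None
        for i, jj in cand:
            if i >= jj:
                continue
            key = (min(order[i], order[jj]), max(order[i], order[jj]))
            if best is None or key < best[0]:
                best = (key, int(i), int(jj))
        _, i, jj = best
        dij = d[i, jj]
        bi = 0.5 * dij + (s[i] - s[jj]) / (2 * (m - 2))
        bj = dij - bi
        vij = v[i, jj]
        mask = np.ones(m, dtype=bool)
        mask[[i, jj]] = False
        if vij > 0:
            lam = 0.5 + float(np.sum(v[jj, mask] - v[i, mask])) / (2 * (m - 2) * vij)
        else:
            lam = 0.5
        lam = min(1.0, max(0.0, lam))

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(bi)
        parent.add_child(nodes[jj])
        nodes[jj].edge.length = float(bj)

        d_new = lam * (d[i, mask] - bi) + (1 - lam) * (d[jj, mask] - bj)
        v_new = lam * v[i, mask] + (1 - lam) * v[jj, mask] - lam * (1 - lam) * vij
        keep = np.nonzero(mask)[0]
        d = d[np.ix_(keep, keep)]
        v = v[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        v = np.pad(v, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = d_new
        v[-1, :-1] = v[:-1, -1] = v_new
        nodes = [nodes[k] for k in keep] + [parent]
        order = [order[k] for k in keep] + [min(order[i], order[jj])]

    # final trifurcation: three-point formulas
    root = dendropy.Node()
    (a, b, c) = (0, 1, 2)
    ba = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    bb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    bc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, length in zip(nodes, (ba, bb, bc)):
        root.add_child(node)
        node.edge.length = float(length)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def leaf_distance_matrix(tree: dendropy.Tree, topological: bool = False) -> tuple[list[str], np.ndarray]:
    """Patristic (or edge-count) distances between all leaves of a tree.

    Implemented as one Dijkstra-free traversal per leaf over the node graph;
    branch lengths of ``None`` count as zero when ``topological`` is False.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): k for k, lf in enumerate(leaves)}
    n = len(leaves)
    out = np.zeros((n, n))

    def neighbours(node):
        for ch in node.child_nodes():
            w = 1.0 if topological else (ch.edge.length or 0.0)
            yield ch, w
        if node.parent_node is not None:
            w = 1.0 if topological else (node.edge.length or 0.0)
            yield node.parent_node, w

    for src in leaves:
        dist = {id(src): 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in neighbours(cur):
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(cur)] + w
                    stack.append(nb)
        i = index[id(src)]
        for lf in leaves:
            out[i, index[id(lf)]] = dist[id(lf)]
    np.fill_diagonal(out, 0.0)
    return labels, out


def tree_residuals(tree: dendropy.Tree, dm: np.ndarray, labels: list[str]) -> np.ndarray:
    """Residual matrix: patristic path length minus observed distance.

    ``residual(i, j) = path_length(i, j) - dm(i, j)``; positive values mean
    the tree overstates the distance (attraction: the samples are more
    similar than the dendrogram suggests), negative values repulsion.
    """
    tip_labels, path = leaf_distance_matrix(tree)
    if set(tip_labels) != set(labels):
        raise ValueError("tree tip set does not match distance-matrix labels")
    perm = [tip_labels.index(lab) for lab in labels]
    path = path[np.ix_(perm, perm)]
    res = path - np.asarray(dm, dtype=float)
    np.fill_diagonal(res, 0.0)
    return res


def mst(dm: np.ndarray, labels: list[str]) -> list[tuple[str, str, float]]:
    """Minimum spanning tree (Prim), deterministic under ties.

    Tied candidate edges are resolved by the lexicographically smallest
    (index, index) pair, so the edge list is reproducible.  Edges are
    returned as ``(label_i, label_j, weight)`` sorted by insertion order.
    """
    d = np.asarray(dm, dtype=float)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("one label per matrix row required")
    if n == 0:
        return []
    in_tree = {0}
    edges: list[tuple[str, str, float]] = []
    while len(in_tree) < n:
        best = None
        for i in sorted(in_tree):
            for j in range(n):
                if j in in_tree:
                    continue
                cand = (d[i, j], min(i, j), max(i, j))
                if best is None or cand < best:
                    best = cand
        w, i, j = best
        edges.append((labels[i], labels[j], float(w)))
        in_tree.add(j if j not in in_tree else i)
    return edges
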