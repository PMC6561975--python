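"""Cluster affiliation graph and its projection to the element graph.

The *cluster affiliation graph* is a weighted bipartite graph linking
each element v_i to every cluster c_beta that contains it, with edge
weight ``a_ib = h(l_beta) = exp(r * l_beta)`` where ``l_beta`` is the
cluster's hierarchy level (0 for flat clusterings, so all weights are
1) and ``r`` is the zooming-lens scaling parameter: negative r
emphasizes coarse levels, positive r fine levels, and r = 0 collapses
a hierarchy into an equally weighted overlapping clustering.

Projecting onto the element vertices yields the *cluster-induced
element graph*, a directed row-stochastic graph whose edge weights

    w_ij = sum_gamma a_ig * a_jg / (sum_kappa a_ik * sum_m a_mg)

equal the landing probability of a two-step random walk
element -> cluster -> element on the affiliation graph.  Co-occurrence
in a large cluster carries less weight than in a small one, and many
memberships dilute the influence of each; under overlap or hierarchy
the weights can be asymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .core import Clustering, ClusteringError, HierarchicalClustering


def compute_levels(h: HierarchicalClustering) -> dict[str, float]:
    """Hierarchy level l_beta in [0, 1] for every cluster.

    The level is the maximum path length from any root to the cluster,
    rescaled by the overall maximum depth D; for a flat (depth-0)
    hierarchy every level is 0.  Raises on cyclic parent structure.
    """
    order = _toposort(h.children)
    depth = {cid: 0 for cid in h.clusters}
    for cid in order:  # parents precede children
        for kid in h.children[cid]:
            depth[kid] = max(depth[kid], depth[cid] + 1)
    max_depth = max(depth.values(), default=0)
    if max_depth == 0:
        return {cid: 0.0 for cid in h.clusters}
    return {cid: d / max_depth for cid, d in depth.items()}


def _toposort(children: dict[str, frozenset[str]]) -> list[str]:
    indeg = {cid: 0 for cid in children}
    for kids in children.values():
        for k in kids:
            indeg[k] += 1
    queue = [cid for cid, d in indeg.items() if d == 0]
    if not queue and children:
        raise ClusteringError("hierarchy has no root (cycle in child links)")
    order: list[str] = []
    while queue:
        cid = queue.pop()
        order.append(cid)
        for k in children[cid]:
            indeg[k] -= 1
            if indeg[k] == 0:
                queue.append(k)
    if len(order) != len(children):
        stuck = sorted(set(children) - set(order))
        raise ClusteringError(f"cycle in hierarchy involving {stuck[:5]}")
    return order


def hierarchy_weight(level: float, r: float) -> float:
    """Affiliation edge weight h(l) = exp(r * l) for level l in [0, 1]."""
    if not 0.0 <= level <= 1.0:
        raise ClusteringError(f"hierarchy level {level} outside [0, 1]")
    return math.exp(r * level)


@dataclass
class AffiliationGraph:
    """Sparse N x K bipartite weight matrix plus its label orderings."""

    matrix: sparse.csr_matrix  # a_ib > 0 iff element i is in cluster b
    elements: tuple[str, ...]
    cluster_ids: tuple[str, ...]
    r: float
    levels: dict[str, float]


def build_affiliation(c: Clustering, r: float = 0.0) -> AffiliationGraph:
    """Affiliation graph of a flat or hierarchical clustering.

    Flat clusterings get unit edge weights; hierarchical clusterings
    weight each membership edge by h(l_beta) = exp(r * l_beta).
    """
    cluster_ids = tuple(c.clusters)
    levels = (
        dict(c.levels)
        if isinstance(c, HierarchicalClustering)
        else {cid: 0.0 for cid in cluster_ids}
    )
    eidx = {e: i for i, e in enumerate(c.elements)}
    rows, cols, vals = [], [], []
    for b, cid in enumerate(cluster_ids):
        w = hierarchy_weight(levels[cid], r)
        for e in c.clusters[cid]:
            rows.append(eidx[e])
            cols.append(b)
            vals.append(w)
    mat = sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(c.n_elements, len(cluster_ids)),
        dtype=float,
    )
    return AffiliationGraph(
        matrix=mat,
        elements=tuple(c.elements),
        cluster_ids=cluster_ids,
        r=r,
        levels=levels,
    )


@dataclass
class ElementGraph:
    """Row-stochastic directed element graph W (sparse N x N)."""

    matrix: sparse.csr_matrix
    elements: tuple[str, ...]

    def to_edgelist(self) -> list[tuple[str, str, float]]:
        coo = self.matrix.tocoo()
        return [
            (self.elements[i], self.elements[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]

    def write_edgelist_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, j, w in self.to_edgelist():
                fh.write(f"{i}\t{j}\t{w!r}\n")


def project_element_graph(g: AffiliationGraph) -> ElementGraph:
    """Project the affiliation graph onto the element vertices.

    W = D^-1 A C^-1 A^T with D = diag(row sums of A) and
    C = diag(column sums of A); rows sum to 1 by construction.
    """
    a = g.matrix
    row_sums = np.asarray(a.sum(axis=1)).ravel()
    if np.any(row_sums <= 0):
        bad = [g.elements[i] for i in np.flatnonzero(row_sums <= 0)][:5]
        raise ClusteringError(f"element(s) with no affiliation: {bad}")
    col_sums = np.asarray(a.sum(axis=0)).ravel()
    d_inv = sparse.diags(1.0 / row_sums)
    c_inv = sparse.diags(1.0 / col_sums)
    w = (d_inv @ a @ c_inv @ a.T).tocsr()
    return ElementGraph(matrix=w, elements=g.elements)


def element_graph(c: Clustering, r: float = 0.0) -> ElementGraph:
    """Convenience: clustering -> cluster-induced element graph."""
    return project_element_graph(build_affiliation(c, r))
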