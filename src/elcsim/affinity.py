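"""Personalized-PageRank element affinities.

For each element v_i the affinity row p_i is the stationary
distribution of a random walk with restart on the cluster-induced
element graph W:

    p_i = (1 - alpha) v_i + alpha * p_i W

where v_i is the indicator vector of the element and 1 - alpha is the
restart probability.  The restart parameter alpha (default 0.90)
controls how far cluster influence propagates through overlaps and
shared hierarchy lineages; the restart mass guarantees
p_ii >= 1 - alpha for every element.

Two solvers are provided.  For a disjoint flat clustering the fixed
point has a closed form — within a cluster of size n the self-affinity
is (1 - alpha) + alpha/n and every co-member receives alpha/n, with
zero affinity across clusters — so the whole matrix is assembled
analytically.  Every other clustering goes through power iteration on
the fixed-point equation, computed once per *membership class* (a
group of elements with identical weighted cluster memberships, whose
rows differ only by exchanging the two elements' indices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .core import Clustering, ClusteringError, HierarchicalClustering
from .graphs import ElementGraph, build_affiliation, element_graph

DEFAULT_ALPHA = 0.90
DEFAULT_TOL = 1e-12
MAX_ITER = 100_000


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the residual tolerance."""


@dataclass
class AffinityMatrix:
    """Per-element PPR rows over a fixed element ordering.

    ``matrix`` is sparse CSR; row i is the affinity distribution p_i of
    ``elements[i]``.  ``provenance`` records whether the rows came from
    the analytic partition solution or the numeric solver.
    """

    matrix: sparse.csr_matrix
    elements: tuple[str, ...]
    alpha: float
    provenance: str  # "analytic" | "numeric"

    def row(self, element: str) -> np.ndarray:
        i = self.elements.index(element)
        return np.asarray(self.matrix[i].todense()).ravel()

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def write_tsv(self, path) -> None:
        dense = self.toarray()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#\t" + "\t".join(self.elements) + "\n")
            for e, row in zip(self.elements, dense):
                fh.write(
                    e + "\t" + "\t".join(repr(v) for v in row.tolist()) + "\n"
                )


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ClusteringError(f"alpha must lie in (0, 1), got {alpha}")


# ---------------------------------------------------------------------------
# Numeric solver


def ppr_row_numeric(
    w: ElementGraph,
    element: str,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
) -> np.ndarray:
    """Solve the restart fixed point for one element by power iteration.

    Iterates p <- (1 - alpha) v_i + alpha p W from p = v_i until the
    max-norm update falls below ``tol`` (cap 10^5 iterations; the
    contraction rate is alpha, so convergence is geometric).
    """
    _check_alpha(alpha)
    if tol <= 0:
        raise ClusteringError(f"tol must be positive, got {tol}")
    i = w.elements.index(element)
    return _power_iterate(w.matrix, i, alpha, tol)


def _power_iterate(
    wmat: sparse.csr_matrix, i: int, alpha: float, tol: float
) -> np.ndarray:
    n = wmat.shape[0]
    v = np.zeros(n)
    v[i] = 1.0
    p = v.copy()
    restart = (1.0 - alpha) * v
    for _ in range(MAX_ITER):
        p_new = restart + alpha * (p @ wmat)
        resid = np.max(np.abs(p_new - p))
        p = p_new
        if resid < tol:
            return p
    raise ConvergenceError(
        f"PPR power iteration did not reach tol={tol} within {MAX_ITER} "
        f"iterations (residual {resid:.3e})"
    )


# ---------------------------------------------------------------------------
# Analytic partition solver


def ppr_partition_analytic(
    c: Clustering, alpha: float = DEFAULT_ALPHA
) -> AffinityMatrix:
    """Closed-form affinity matrix for a disjoint flat clustering.

    Within a cluster of size n: p_ii = (1 - alpha) + alpha/n and
    p_ij = alpha/n for co-members; affinities across clusters are 0.
    This is the exact fixed point of the restart equation on the
    partition's element graph (whose rows are uniform over each
    cluster block).
    """
    _check_alpha(alpha)
    if isinstance(c, HierarchicalClustering) or not c.is_partition():
        raise ClusteringError(
            "analytic solver requires a disjoint flat clustering"
        )
    n_el = c.n_elements
    eidx = {e: i for i, e in enumerate(c.elements)}
    rows, cols, vals = [], [], []
    for members in c.clusters.values():
        idx = [eidx[e] for e in members]
        n = len(idx)
        off = alpha / n
        for i in idx:
            for j in idx:
                rows.append(i)
                cols.append(j)
                vals.append(off + (1.0 - alpha if i == j else 0.0))
    mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n_el, n_el))
    return AffinityMatrix(
        matrix=mat,
        elements=tuple(c.elements),
        alpha=alpha,
        provenance="analytic",
    )


# ---------------------------------------------------------------------------
# Membership classes


@dataclass
class MembershipClasses:
    """Groups of elements with identical weighted membership sets."""

    classes: list[tuple[str, ...]]

    def as_sets(self) -> list[frozenset[str]]:
        return [frozenset(c) for c in self.classes]


def membership_classes(c: Clustering, r: float = 0.0) -> MembershipClasses:
    """Partition the elements by exact weighted-membership equality.

    Two elements share a class iff they belong to exactly the same
    clusters; for hierarchies the cluster weights h(l) are part of the
    key, though with a single global ``r`` equal membership sets imply
    equal weights.
    """
    if isinstance(c, HierarchicalClustering):
        import math

        key = lambda e: frozenset(
            (cid, round(math.exp(r * c.levels[cid]), 15))
            for cid in c.memberships[e]
        )
    else:
        key = lambda e: c.memberships[e]
    groups: dict[object, list[str]] = {}
    for e in c.elements:
        groups.setdefault(key(e), []).append(e)
    return MembershipClasses(classes=[tuple(g) for g in groups.values()])


# ---------------------------------------------------------------------------
# Dispatch


def affinity_matrix(
    c: Clustering,
    alpha: float = DEFAULT_ALPHA,
    r: float = 0.0,
    tol: float = DEFAULT_TOL,
) -> AffinityMatrix:
    """Affinity matrix of a clustering, choosing the cheapest exact route.

    Disjoint flat clusterings use the analytic closed form; overlapping
    or hierarchical clusterings use power iteration, solved once per
    membership class and propagated to class mates by the index
    exchange permutation.
    """
    _check_alpha(alpha)
    if not isinstance(c, HierarchicalClustering) and c.is_partition():
        return ppr_partition_analytic(c, alpha)
    w = element_graph(c, r)
    eidx = {e: i for i, e in enumerate(w.elements)}
    n = len(w.elements)
    out_rows = []
    out_cols = []
    out_vals = []
    for group in membership_classes(c, r).classes:
        rep = group[0]
        i0 = eidx[rep]
        p = _power_iterate(w.matrix, i0, alpha, tol)
        nz = np.flatnonzero(p)
        for e in group:
            i = eidx[e]
            # exchange permutation of indices i0 <-> i maps rep's row to e's
            row = p
            cols = nz
            if i != i0:
                row = p.copy()
                row[i0], row[i] = row[i], row[i0]
                cols = np.flatnonzero(row)
            out_rows.extend([i] * len(cols))
            out_cols.extend(cols.tolist())
            out_vals.extend(row[cols].tolist())
    mat = sparse.csr_matrix((out_vals, (out_rows, out_cols)), shape=(n, n))
    return AffinityMatrix(
        matrix=mat,
        elements=tuple(w.elements),
        alpha=alpha,
        provenance="numeric",
    )
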