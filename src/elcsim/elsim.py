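"""Element-centric similarity, agreement and frustration.

Each element is compared through the affinity distributions induced by
the two clusterings, using the L1 metric corrected for the restart
mass it can never move (an element holds at least 1 - alpha of
probability on itself in both rows, so the attainable L1 range is
[0, 2 alpha]):

    S_i(A, B) = 1 - (1 / 2 alpha) * sum_j | p^A_ij - p^B_ij |

The clustering-level score S(A, B) is the plain average of the S_i;
the L1 choice makes the score invariant to the magnitude of the
probability values, treating clusters of all sizes equally.

Over a set of clusterings two per-element consensus statistics follow:
the *average agreement* of a reference clustering with the set (mean
S_i against each member) and the *frustration* of the set (mean S_i
over all unordered pairs).  Note the raw pairwise mean is largest for
perfectly consistent sets; reports that want "high = inconsistent" can
use its complement, exposed here as ``frustration_score``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .affinity import DEFAULT_ALPHA, DEFAULT_TOL, AffinityMatrix, affinity_matrix
from .core import Clustering, ClusteringError, align_universes


@dataclass
class ElementScores:
    """Per-element similarity values and their aggregate."""

    elements: tuple[str, ...]
    scores: np.ndarray  # S_i in [0, 1], aligned with ``elements``
    aggregate: float  # mean of scores
    alpha: float
    r_a: float
    r_b: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.elements, self.scores.tolist()))

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e, s in zip(self.elements, self.scores.tolist()):
                fh.write(f"{e}\t{s!r}\n")


def elementwise_similarity(
    pa: AffinityMatrix, pb: AffinityMatrix
) -> ElementScores:
    """Corrected-L1 similarity of each element's two affinity rows.

    The two matrices must share the element universe and restart
    parameter; if their element orderings differ, ``pb`` is permuted
    onto ``pa``'s ordering.
    """
    if pa.alpha != pb.alpha:
        raise ClusteringError(
            f"alpha mismatch: {pa.alpha} vs {pb.alpha}"
        )
    if set(pa.elements) != set(pb.elements):
        raise ClusteringError("affinity matrices cover different elements")
    mb = pb.matrix
    if pa.elements != pb.elements:
        pos_b = {e: i for i, e in enumerate(pb.elements)}
        perm = np.array([pos_b[e] for e in pa.elements])
        mb = mb[perm][:, perm]
    diff = abs(pa.matrix - mb)
    l1 = np.asarray(diff.sum(axis=1)).ravel()
    scores = np.clip(1.0 - l1 / (2.0 * pa.alpha), 0.0, 1.0)
    return ElementScores(
        elements=pa.elements,
        scores=scores,
        aggregate=float(scores.mean()),
        alpha=pa.alpha,
        r_a=np.nan,
        r_b=np.nan,
    )


def similarity(
    a: Clustering,
    b: Clustering,
    alpha: float = DEFAULT_ALPHA,
    r: float = 0.0,
    tol: float = DEFAULT_TOL,
    align: str = "strict",
) -> ElementScores:
    """Element-centric similarity S(A, B) with per-element detail.

    A single zooming-lens parameter ``r`` applies to both clusterings;
    a flat clustering sits entirely at level 0, so its affiliation
    weights are 1 for every ``r``.  The result's ``aggregate`` is the
    scalar S; symmetry S(A, B) = S(B, A) and the identity S(A, A) = 1
    follow from the definition.
    """
    a, b = align_universes(a, b, align)
    pa = affinity_matrix(a, alpha=alpha, r=r, tol=tol)
    pb = affinity_matrix(b, alpha=alpha, r=r, tol=tol)
    out = elementwise_similarity(pa, pb)
    out.r_a = r
    out.r_b = r
    return out


def elsim(
    a: Clustering,
    b: Clustering,
    alpha: float = DEFAULT_ALPHA,
    r: float = 0.0,
    **kw,
) -> float:
    """Scalar element-centric similarity S(A, B)."""
    return similarity(a, b, alpha=alpha, r=r, **kw).aggregate


def average_agreement(
    reference: Clustering,
    clusterings: list[Clustering],
    alpha: float = DEFAULT_ALPHA,
    r: float = 0.0,
    tol: float = DEFAULT_TOL,
) -> ElementScores:
    """Mean element-wise similarity of a reference against a set.

    value_i = (1/T) sum_j S_i(reference, R_j) over the T clusterings.
    """
    if not clusterings:
        raise ClusteringError("average agreement needs at least one clustering")
    p_ref = affinity_matrix(reference, alpha=alpha, r=r, tol=tol)
    acc = np.zeros(len(p_ref.elements))
    for c in clusterings:
        align_universes(reference, c, "strict")
        p_c = affinity_matrix(c, alpha=alpha, r=r, tol=tol)
        acc += elementwise_similarity(p_ref, p_c).scores
    acc /= len(clusterings)
    return ElementScores(
        elements=p_ref.elements,
        scores=acc,
        aggregate=float(acc.mean()),
        alpha=alpha,
        r_a=r,
        r_b=r,
    )


def frustration(
    clusterings: list[Clustering],
    alpha: float = DEFAULT_ALPHA,
    r: float = 0.0,
    tol: float = DEFAULT_TOL,
) -> ElementScores:
    """Mean pairwise element-wise similarity within a set of clusterings.

    value_i = (1/C(T,2)) sum_{j<k} S_i(R_j, R_k); equal to 1 for every
    element iff all clusterings group it identically.  The complement
    1 - value_i (high = inconsistently grouped) is available through
    :func:`frustration_score`.
    """
    if len(clusterings) < 2:
        raise ClusteringError("frustration needs at least two clusterings")
    first = clusterings[0]
    for c in clusterings[1:]:
        align_universes(first, c, "strict")
    mats = [
        affinity_matrix(c, alpha=alpha, r=r, tol=tol) for c in clusterings
    ]
    acc = np.zeros(len(mats[0].elements))
    n_pairs = 0
    for pa, pb in combinations(mats, 2):
        acc += elementwise_similarity(pa, pb).scores
        n_pairs += 1
    acc /= n_pairs
    return ElementScores(
        elements=mats[0].elements,
        scores=acc,
        aggregate=float(acc.mean()),
        alpha=alpha,
        r_a=r,
        r_b=r,
    )


def frustration_score(scores: ElementScores) -> ElementScores:
    """Complement of the raw pairwise consistency (high = frustrated)."""
    inv = 1.0 - scores.scores
    return ElementScores(
        elements=scores.elements,
        scores=inv,
        aggregate=float(inv.mean()),
        alpha=scores.alpha,
        r_a=scores.r_a,
        r_b=scores.r_b,
    )


def ranked_scores(scores: ElementScores) -> list[tuple[str, float]]:
    """Element-score pairs in descending score order, ties by element id."""
    return sorted(
        zip(scores.elements, scores.scores.tolist()),
        key=lambda kv: (-kv[1], kv[0]),
    )
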