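"""Classic clustering-comparison measures.

Pair-counting family (Rand, Jaccard, F, Fowlkes–Mallows, adjusted
Rand), information-theoretic family (NMI, variation of information),
matching-based percentage matching, and the two cover-capable
measures: the LFK overlapping NMI and the Omega index.

Pair-counting and information-theoretic measures are defined here for
disjoint clusterings (partitions); ONMI and Omega accept overlaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment

from .core import Clustering, ClusteringError


def _require_partitions(*cs: Clustering, what: str) -> None:
    for c in cs:
        if not c.is_partition():
            raise ClusteringError(f"{what} is defined here only for partitions")


def _labels(c: Clustering) -> np.ndarray:
    """Integer cluster label per element (partitions only)."""
    cid_index = {cid: k for k, cid in enumerate(c.clusters)}
    return np.array(
        [cid_index[next(iter(c.memberships[e]))] for e in c.elements]
    )


# ---------------------------------------------------------------------------
# Contingency table and pair counts


@dataclass
class ContingencyTable:
    """Cross-tabulation n_kl = |A_k ∩ B_l| with marginals."""

    counts: np.ndarray  # K_A x K_B
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def contingency_table(a: Clustering, b: Clustering) -> ContingencyTable:
    _require_partitions(a, b, what="the contingency table")
    if set(a.elements) != set(b.elements):
        raise ClusteringError("contingency table needs aligned universes")
    la = _labels(a)
    order = {e: i for i, e in enumerate(a.elements)}
    lb_by_a_order = np.empty(len(la), dtype=int)
    lb = _labels(b)
    for e, lab in zip(b.elements, lb):
        lb_by_a_order[order[e]] = lab
    ka, kb = a.n_clusters, b.n_clusters
    counts = sparse.coo_matrix(
        (np.ones(len(la)), (la, lb_by_a_order)), shape=(ka, kb)
    ).toarray()
    return ContingencyTable(
        counts=counts,
        row_ids=tuple(a.clusters),
        col_ids=tuple(b.clusters),
    )


@dataclass
class PairCounts:
    """Agreement counts over all C(N,2) unordered element pairs."""

    n11: int  # co-clustered in both
    n10: int  # co-clustered in A only
    n01: int  # co-clustered in B only
    n00: int  # co-clustered in neither

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) // 2


def pair_counts(a: Clustering, b: Clustering) -> PairCounts:
    """Exact pair-agreement counts from the contingency table."""
    ct = contingency_table(a, b)
    n = ct.n
    total = n * (n - 1) // 2
    n11 = int(_comb2(ct.counts.astype(np.int64)).sum())
    pairs_a = int(_comb2(ct.row_marginals.astype(np.int64)).sum())
    pairs_b = int(_comb2(ct.col_marginals.astype(np.int64)).sum())
    n10 = pairs_a - n11
    n01 = pairs_b - n11
    return PairCounts(n11=n11, n10=n10, n01=n01, n00=total - n11 - n10 - n01)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(
            f"degenerate denominator in {what}; returning 0", stacklevel=3
        )
        return 0.0
    return num / den


def pair_measures(pc: PairCounts) -> dict[str, float]:
    """All pair-counting indices from one set of counts.

    The adjusted Rand index uses the Hubert–Arabie permutation-model
    expectation, written directly in pair counts as
    2(n11 n00 − n10 n01) / ((n11+n10)(n10+n00) + (n11+n01)(n01+n00)).
    Degenerate denominators (e.g. no co-clustered pairs at all) give 0
    with a warning.
    """
    a, b, c, d = pc.n11, pc.n10, pc.n01, pc.n00
    precision = _safe_div(a, a + c, "precision")
    recall = _safe_div(a, a + b, "recall")
    f = (
        _safe_div(2 * precision * recall, precision + recall, "F measure")
        if (precision + recall) > 0
        else _safe_div(0.0, 0.0, "F measure")
    )
    ari_den = (a + b) * (b + d) + (a + c) * (c + d)
    return {
        "rand": _safe_div(a + d, pc.total, "Rand index"),
        "jaccard": _safe_div(a, a + b + c, "Jaccard index"),
        "f_measure": f,
        "fowlkes_mallows": math.sqrt(precision * recall),
        "ari": _safe_div(2.0 * (a * d - b * c), ari_den, "adjusted Rand index"),
    }


# ---------------------------------------------------------------------------
# Information-theoretic measures (partitions)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _mutual_information(ct: ContingencyTable) -> tuple[float, float, float]:
    n = ct.n
    p_ab = ct.counts / n
    h_a = _entropy(ct.row_marginals / n)
    h_b = _entropy(ct.col_marginals / n)
    nz = p_ab > 0
    outer = np.outer(ct.row_marginals / n, ct.col_marginals / n)
    mi = float((p_ab[nz] * np.log(p_ab[nz] / outer[nz])).sum())
    return mi, h_a, h_b


def nmi(a: Clustering, b: Clustering, normalization: str = "sum") -> float:
    """Normalized mutual information of two partitions.

    Default normalization is 2 I / (H_A + H_B); ``max`` and ``sqrt``
    variants are available.  When both partitions carry zero entropy
    (one cluster each over the same universe, hence identical), NMI is
    defined as 1.
    """
    ct = contingency_table(a, b)
    mi, h_a, h_b = _mutual_information(ct)
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if normalization == "sum":
        den = (h_a + h_b) / 2.0
    elif normalization == "max":
        den = max(h_a, h_b)
    elif normalization == "sqrt":
        den = math.sqrt(h_a * h_b)
    else:
        raise ClusteringError(f"unknown NMI normalization {normalization!r}")
    if den == 0.0:
        return 0.0
    return min(mi / den, 1.0)


def vi(a: Clustering, b: Clustering) -> float:
    """Variation of information H(A|B) + H(B|A), in nats (a metric)."""
    ct = contingency_table(a, b)
    mi, h_a, h_b = _mutual_information(ct)
    return max(h_a + h_b - 2.0 * mi, 0.0)


# ---------------------------------------------------------------------------
# Percentage matching


def pm(a: Clustering, b: Clustering, greedy: bool = False) -> float:
    """Percentage matching: best-match cluster overlap divided by N.

    The default pairs clusters by an optimal one-to-one assignment
    (maximizing total matched elements); ``greedy`` instead repeatedly
    takes the largest remaining overlap.  A set-matching measure: it
    ignores what happens in the unmatched parts of clusters.
    """
    ct = contingency_table(a, b)
    if greedy:
        counts = ct.counts.copy()
        matched = 0.0
        for _ in range(min(counts.shape)):
            k, l = np.unravel_index(np.argmax(counts), counts.shape)
            if counts[k, l] <= 0:
                break
            matched += counts[k, l]
            counts[k, :] = -1
            counts[:, l] = -1
        return matched / ct.n
    rows, cols = linear_sum_assignment(-ct.counts)
    return float(ct.counts[rows, cols].sum()) / ct.n


# ---------------------------------------------------------------------------
# Overlap-capable measures


def _binary_membership(c: Clustering) -> np.ndarray:
    """Dense N x K 0/1 membership matrix in element order."""
    m = np.zeros((c.n_elements, c.n_clusters), dtype=np.int64)
    cid_index = {cid: k for k, cid in enumerate(c.clusters)}
    for i, e in enumerate(c.elements):
        for cid in c.memberships[e]:
            m[i, cid_index[cid]] = 1
    return m


def _h(w: float, n: float) -> float:
    return 0.0 if w <= 0 else -(w / n) * math.log(w / n)


def onmi(a: Clustering, b: Clustering) -> float:
    """Overlapping NMI for covers (LFK variant).

    Each cluster is a binary membership variable over the N elements.
    For each cluster X_k of A the best conditional entropy
    H(X_k | Y_l) over B's clusters is taken, subject to the
    admissibility constraint h(11) + h(00) >= h(01) + h(10) that
    forbids matching a cluster with a complement-like one; when no
    admissible match exists the conditional entropy is H(X_k).  The
    normalized conditional entropies are averaged in both directions:
    ONMI = 1 − [H_norm(A|B) + H_norm(B|A)] / 2.
    """
    if set(a.elements) != set(b.elements):
        raise ClusteringError("ONMI needs aligned universes")
    order = list(a.elements)
    ea = _binary_membership(a)
    pos = {e: i for i, e in enumerate(b.elements)}
    perm = np.array([pos[e] for e in order])
    eb = _binary_membership(b)[perm]
    n = len(order)

    def normalized_cond(x: np.ndarray, y: np.ndarray) -> float:
        """Mean over x's clusters of H*(X_k|Y)/H(X_k)."""
        sizes_x = x.sum(axis=0)
        sizes_y = y.sum(axis=0)
        inter = x.T @ y  # K_x x K_y intersection counts
        terms = []
        for k in range(x.shape[1]):
            hx = _h(sizes_x[k], n) + _h(n - sizes_x[k], n)
            if hx == 0.0:
                # constant membership variable (cluster spans the whole
                # universe): it carries no information, so it only counts
                # as explained if the other cover holds the same cluster
                identical = any(
                    sizes_y[l] == sizes_x[k] and inter[k, l] == sizes_x[k]
                    for l in range(y.shape[1])
                )
                terms.append(0.0 if identical else 1.0)
                continue
            best = hx
            for l in range(y.shape[1]):
                d = inter[k, l]  # in both
                c_ = sizes_x[k] - d  # X only
                b_ = sizes_y[l] - d  # Y only
                a_ = n - sizes_x[k] - sizes_y[l] + d  # neither
                if _h(d, n) + _h(a_, n) < _h(b_, n) + _h(c_, n):
                    continue  # inadmissible match
                hy = _h(sizes_y[l], n) + _h(n - sizes_y[l], n)
                hxy = _h(a_, n) + _h(b_, n) + _h(c_, n) + _h(d, n)
                best = min(best, hxy - hy)
            terms.append(max(best, 0.0) / hx)
        return float(np.mean(terms))

    return 1.0 - 0.5 * (normalized_cond(ea, eb) + normalized_cond(eb, ea))


def omega(a: Clustering, b: Clustering) -> float:
    """Omega index: chance-adjusted pair agreement for covers.

    Two elements "agree" when they share the same *number* of common
    clusters in both clusterings; the observed agreement rate is
    adjusted by the expectation under independent shuffling of the
    pairs' shared-cluster counts.  On partitions this reduces exactly
    to the adjusted Rand index.  Identical clusterings score 1 by
    convention even when the chance adjustment degenerates.
    """
    if set(a.elements) != set(b.elements):
        raise ClusteringError("Omega needs aligned universes")
    order = list(a.elements)
    ea = _binary_membership(a)
    pos = {e: i for i, e in enumerate(b.elements)}
    perm = np.array([pos[e] for e in order])
    eb = _binary_membership(b)[perm]
    ta = ea @ ea.T  # pairwise shared-cluster counts
    tb = eb @ eb.T
    iu = np.triu_indices(len(order), k=1)
    ta, tb = ta[iu], tb[iu]
    m = ta.size
    obs = float(np.mean(ta == tb))
    max_t = int(max(ta.max(initial=0), tb.max(initial=0)))
    counts_a = np.bincount(ta, minlength=max_t + 1)
    counts_b = np.bincount(tb, minlength=max_t + 1)
    exp = float((counts_a * counts_b).sum()) / (m * m)
    if 1.0 - exp == 0.0:
        return 1.0 if obs == 1.0 else 0.0
    return (obs - exp) / (1.0 - exp)


# ---------------------------------------------------------------------------
# Measure registry (shared by CLI and experiment runner)


def _m_rand(a, b):
    return pair_measures(pair_counts(a, b))["rand"]


def _m_ari(a, b):
    return pair_measures(pair_counts(a, b))["ari"]


def _m_jaccard(a, b):
    return pair_measures(pair_counts(a, b))["jaccard"]


def _m_f(a, b):
    return pair_measures(pair_counts(a, b))["f_measure"]


def _m_fm(a, b):
    return pair_measures(pair_counts(a, b))["fowlkes_mallows"]


def all_measures() -> dict[str, object]:
    """Name -> callable(a, b) -> float for every comparison measure."""
    from .elsim import elsim

    return {
        "elsim": elsim,
        "rand": _m_rand,
        "ari": _m_ari,
        "jaccard": _m_jaccard,
        "f": _m_f,
        "fm": _m_fm,
        "pm": pm,
        "nmi": nmi,
        "vi": vi,
        "onmi": onmi,
        "omega": omega,
    }
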