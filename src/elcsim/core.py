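"""Clustering data model, validation, canonicalization and file I/O.

A *clustering* assigns each of N elements to one or more of K clusters.
When every element has exactly one membership the clustering is a
partition; multiple memberships per element encode overlap.  A
*hierarchical clustering* additionally carries an acyclic parent/child
structure over the clusters, and each cluster a level ``l`` in [0, 1]
(0 at the roots, 1 at the deepest clusters).

Canonical on-disk formats:

* membership TSV — UTF-8, ``#`` comments, one ``element<TAB>cluster``
  row per membership; duplicate rows collapse (membership is a set
  property);
* hierarchy JSON — ``{"clusters": {"<id>": {"members": [...],
  "children": [...]}}}``; a record without ``children`` is a leaf.

Element and cluster ids are opaque strings; nothing downstream depends
on their ordering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class ClusteringError(ValueError):
    """Invalid clustering structure or arguments."""


class ParseError(ClusteringError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class UniverseMismatchError(ClusteringError):
    """Two clusterings do not share the same element set."""

    def __init__(self, only_a: set[str], only_b: set[str]):
        self.only_a = frozenset(only_a)
        self.only_b = frozenset(only_b)
        super().__init__(
            "element universes differ: "
            f"{len(only_a)} element(s) only in A {_preview(only_a)}, "
            f"{len(only_b)} only in B {_preview(only_b)}"
        )


def _preview(ids: Iterable[str], k: int = 5) -> str:
    ids = sorted(ids)
    head = ", ".join(ids[:k])
    return f"[{head}{', ...' if len(ids) > k else ''}]"


class Clustering:
    """A flat (possibly overlapping) clustering of labeled elements.

    Parameters
    ----------
    clusters
        Map cluster-id -> iterable of member element ids.  Every cluster
        must be nonempty; the element universe is the union of all
        clusters unless ``elements`` widens it (widening is rejected —
        every element must be covered).
    elements
        Optional explicit element ordering.  Defaults to first-seen
        order over the cluster map.
    """

    def __init__(
        self,
        clusters: Mapping[str, Iterable[str]],
        elements: Sequence[str] | None = None,
    ):
        if not clusters:
            raise ClusteringError("a clustering needs at least one cluster")
        self.clusters: dict[str, frozenset[str]] = {}
        seen: dict[str, None] = {}
        for cid, members in clusters.items():
            mem = frozenset(str(m) for m in members)
            if not mem:
                raise ClusteringError(f"cluster {cid!r} is empty")
            self.clusters[str(cid)] = mem
            for m in members:
                seen.setdefault(str(m), None)
        if elements is not None:
            order = [str(e) for e in elements]
            if set(order) != set(seen):
                missing = set(order) - set(seen)
                extra = set(seen) - set(order)
                if missing:
                    raise ClusteringError(
                        f"uncovered element(s) {_preview(missing)}"
                    )
                raise ClusteringError(
                    f"elements absent from universe {_preview(extra)}"
                )
            self.elements: tuple[str, ...] = tuple(order)
        else:
            self.elements = tuple(seen)
        self._index = {e: i for i, e in enumerate(self.elements)}
        memberships: dict[str, set[str]] = {e: set() for e in self.elements}
        for cid, mem in self.clusters.items():
            for e in mem:
                memberships[e].add(cid)
        self.memberships: dict[str, frozenset[str]] = {
            e: frozenset(cs) for e, cs in memberships.items()
        }

    # -- basic properties -------------------------------------------------

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def index(self, element: str) -> int:
        return self._index[element]

    def is_partition(self) -> bool:
        """True iff every element has exactly one membership."""
        return all(len(cs) == 1 for cs in self.memberships.values())

    def is_hierarchical(self) -> bool:
        return False

    def membership_count(self) -> int:
        """Total number of (element, cluster) memberships."""
        return sum(len(m) for m in self.clusters.values())

    # -- conveniences ------------------------------------------------------

    def relabeled(
        self,
        element_map: Mapping[str, str] | None = None,
        cluster_map: Mapping[str, str] | None = None,
    ) -> "Clustering":
        """Return a copy with element and/or cluster ids renamed."""
        emap = dict(element_map) if element_map else {}
        cmap = dict(cluster_map) if cluster_map else {}
        clusters = {
            cmap.get(cid, cid): [emap.get(e, e) for e in mem]
            for cid, mem in self.clusters.items()
        }
        elements = [emap.get(e, e) for e in self.elements]
        return Clustering(clusters, elements)

    def to_membership_list(self) -> list[tuple[str, str]]:
        rows = []
        for e in self.elements:
            for cid in sorted(self.memberships[e]):
                rows.append((e, cid))
        return rows

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clustering):
            return NotImplemented
        return (
            set(self.elements) == set(other.elements)
            and sorted(self.clusters.values(), key=sorted)
            == sorted(other.clusters.values(), key=sorted)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<{type(self).__name__} N={self.n_elements} K={self.n_clusters}"
            f"{'' if self.is_partition() else ' overlapping'}>"
        )


class HierarchicalClustering(Clustering):
    """A clustering whose clusters form an acyclic parent/child DAG.

    ``children`` maps cluster-id -> child cluster-ids; roots are the
    clusters with no parent.  Levels are assigned by rescaling the
    longest root-to-cluster path length to [0, 1] (see
    :func:`elcsim.graphs.compute_levels`); a depth-0 (flat) hierarchy
    has all levels 0.
    """

    def __init__(
        self,
        clusters: Mapping[str, Iterable[str]],
        children: Mapping[str, Iterable[str]],
        elements: Sequence[str] | None = None,
    ):
        super().__init__(clusters, elements)
        self.children: dict[str, frozenset[str]] = {
            cid: frozenset() for cid in self.clusters
        }
        for cid, kids in children.items():
            cid = str(cid)
            if cid not in self.clusters:
                raise ClusteringError(f"unknown cluster id {cid!r} in hierarchy")
            kidset = frozenset(str(k) for k in kids)
            undefined = kidset - self.clusters.keys()
            if undefined:
                raise ClusteringError(
                    f"cluster {cid!r} references undefined child(ren) "
                    f"{_preview(undefined)}"
                )
            self.children[cid] = kidset
        self.parents: dict[str, frozenset[str]] = {
            cid: frozenset() for cid in self.clusters
        }
        par: dict[str, set[str]] = {cid: set() for cid in self.clusters}
        for cid, kids in self.children.items():
            for k in kids:
                par[k].add(cid)
        self.parents = {cid: frozenset(p) for cid, p in par.items()}
        # computed here so every instance carries consistent levels
        from .graphs import compute_levels

        self.levels: dict[str, float] = compute_levels(self)

    def is_hierarchical(self) -> bool:
        return True

    def roots(self) -> list[str]:
        return [cid for cid, p in self.parents.items() if not p]

    def level_slice(self, level: float, atol: float = 1e-9) -> Clustering:
        """Flat clustering of the clusters whose level equals ``level``."""
        picked = {
            cid: self.clusters[cid]
            for cid in self.clusters
            if abs(self.levels[cid] - level) <= atol
        }
        if not picked:
            raise ClusteringError(f"no clusters at level {level}")
        return Clustering(picked)

    def as_flat(self) -> Clustering:
        """Drop the hierarchy: same clusters as an overlapping clustering."""
        return Clustering(self.clusters, self.elements)


# ---------------------------------------------------------------------------
# File I/O


def read_membership_tsv(path) -> Clustering:
    """Read a membership TSV file (``element<TAB>cluster`` rows).

    Lines that are empty or start with ``#`` are ignored.  Duplicate
    membership rows collapse to a single membership.
    """
    clusters: dict[str, list[str]] = {}
    order: dict[str, None] = {}
    n_rows = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(
                    f"expected 'element<TAB>cluster', got {line!r}", lineno
                )
            element, cid = parts
            clusters.setdefault(cid, []).append(element)
            order.setdefault(element, None)
            n_rows += 1
    if n_rows == 0:
        raise ParseError(f"no membership rows in {path}")
    return Clustering(clusters, elements=list(order))


def write_membership_tsv(c: Clustering, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for element, cid in c.to_membership_list():
            fh.write(f"{element}\t{cid}\n")


def read_hierarchy_json(path) -> HierarchicalClustering:
    """Read a hierarchy JSON document.

    Schema: ``{"clusters": {"<id>": {"members": [..], "children": [..]}}}``.
    ``children`` may be absent (leaf).  A cluster listed only as a child
    must still have its own record.  Cycles in the child links are a
    structural error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "clusters" not in doc:
        raise ParseError(f"{path}: expected a JSON object with a 'clusters' key")
    records = doc["clusters"]
    clusters: dict[str, list[str]] = {}
    children: dict[str, list[str]] = {}
    for cid, rec in records.items():
        members = list(rec.get("members", []))
        kids = list(rec.get("children", []))
        for k in kids:
            if k not in records:
                raise ClusteringError(
                    f"cluster {cid!r} references undefined child {k!r}"
                )
        # a parent's member set may be given implicitly as the union of
        # its descendants' members
        clusters[cid] = members
        children[cid] = kids
    _fill_implicit_members(clusters, children)
    return HierarchicalClustering(clusters, children)


def _fill_implicit_members(
    clusters: dict[str, list[str]], children: dict[str, list[str]]
) -> None:
    """Replace empty member lists of internal clusters by descendant unions."""
    memo: dict[str, set[str]] = {}
    active: set[str] = set()

    def resolve(cid: str) -> set[str]:
        if cid in memo:
            return memo[cid]
        if cid in active:
            raise ClusteringError(f"cycle in hierarchy at cluster {cid!r}")
        active.add(cid)
        members = set(clusters[cid])
        if not members and children.get(cid):
            for k in children[cid]:
                members |= resolve(k)
        else:
            for k in children.get(cid, []):
                resolve(k)
        active.discard(cid)
        memo[cid] = members
        return members

    for cid in list(clusters):
        resolve(cid)
    for cid in clusters:
        if not clusters[cid]:
            clusters[cid] = sorted(memo[cid])


# ---------------------------------------------------------------------------
# Validation and alignment


@dataclass
class ValidationReport:
    """Diagnostics for a clustering; ``passes`` iff the invariants hold."""

    n_elements: int
    n_clusters: int
    n_memberships: int
    n_overlapping_elements: int
    max_memberships_per_element: int
    issues: list[str] = field(default_factory=list)

    @property
    def passes(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        lines = [
            f"elements: {self.n_elements}",
            f"clusters: {self.n_clusters}",
            f"memberships: {self.n_memberships}",
            f"overlapping elements: {self.n_overlapping_elements}",
            f"max memberships/element: {self.max_memberships_per_element}",
        ]
        if self.issues:
            lines.append("issues:")
            lines.extend(f"  - {i}" for i in self.issues)
        else:
            lines.append("issues: none")
        return "\n".join(lines)


def validate(
    clusters: Mapping[str, Iterable[str]] | Clustering,
    elements: Sequence[str] | None = None,
) -> ValidationReport:
    """Report structural diagnostics without raising.

    Accepts either a built :class:`Clustering` (whose constructor already
    enforces the invariants, so the report simply summarizes it) or a raw
    cluster map plus an optional explicit universe, in which case empty
    clusters and uncovered elements are reported as issues.
    """
    issues: list[str] = []
    if isinstance(clusters, Clustering):
        cmap: Mapping[str, Iterable[str]] = clusters.clusters
        universe = set(clusters.elements)
    else:
        cmap = clusters
        universe = set(elements) if elements is not None else set()
        for members in cmap.values():
            universe |= set(members)
    covered: set[str] = set()
    counts: dict[str, int] = {e: 0 for e in universe}
    n_mem = 0
    for cid, members in cmap.items():
        mem = set(members)
        if not mem:
            issues.append(f"empty cluster {cid!r}")
        covered |= mem
        n_mem += len(mem)
        for e in mem:
            counts[e] = counts.get(e, 0) + 1
    for e in sorted(universe - covered):
        issues.append(f"uncovered element {e!r}")
    n_overlap = sum(1 for v in counts.values() if v > 1)
    return ValidationReport(
        n_elements=len(universe),
        n_clusters=len(cmap),
        n_memberships=n_mem,
        n_overlapping_elements=n_overlap,
        max_memberships_per_element=max(counts.values(), default=0),
        issues=issues,
    )


def align_universes(
    a: Clustering, b: Clustering, policy: str = "strict"
) -> tuple[Clustering, Clustering]:
    """Bring two clusterings onto a common element universe.

    ``strict`` requires identical element sets and returns the inputs
    unchanged.  ``pad-singletons`` adds every element missing from one
    clustering to it as a new singleton cluster, so that unmatched
    elements contribute their own isolated group rather than being
    dropped.
    """
    only_a = set(a.elements) - set(b.elements)
    only_b = set(b.elements) - set(a.elements)
    if policy == "strict":
        if only_a or only_b:
            raise UniverseMismatchError(only_a, only_b)
        return a, b
    if policy != "pad-singletons":
        raise ClusteringError(f"unknown alignment policy {policy!r}")

    def pad(c: Clustering, missing: set[str]) -> Clustering:
        if not missing:
            return c
        clusters = {cid: set(mem) for cid, mem in c.clusters.items()}
        for e in sorted(missing):
            cid = f"__singleton_{e}"
            while cid in clusters:
                cid += "_"
            clusters[cid] = {e}
        return Clustering(clusters, list(c.elements) + sorted(missing))

    return pad(a, only_b), pad(b, only_a)


# ---------------------------------------------------------------------------
# Size sequence


@dataclass(frozen=True)
class SizeSequence:
    """Cluster sizes in descending order plus the Shannon entropy (bits)
    of the normalized sequence q_beta = |c_beta| / sum |c_gamma|."""

    sizes: tuple[int, ...]
    entropy: float


def size_sequence(c: Clustering) -> SizeSequence:
    sizes = tuple(sorted((len(m) for m in c.clusters.values()), reverse=True))
    total = sum(sizes)
    entropy = -sum(
        (s / total) * math.log2(s / total) for s in sizes if s > 0
    )
    # clamp the -0.0 that a single cluster produces
    return SizeSequence(sizes=sizes, entropy=max(entropy, 0.0))
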