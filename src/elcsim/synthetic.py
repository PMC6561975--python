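"""Synthetic clustering generators and bias-scenario runners.

These generators reproduce the benchmark conditions used to probe
clustering-comparison measures for bias:

* ``randomized_membership`` — a 1,024-element / 32-equal-cluster
  partition compared against itself after a fraction of element
  memberships is shuffled (size sequence preserved exactly);
* ``skewed_sizes`` — starting from the same partition with memberships
  randomized, a preferential-attachment walk reassigns one uniformly
  chosen element per step to a cluster picked proportionally to its
  current size, so the size-sequence entropy drifts down as clusters
  concentrate;
* ``num_clusters`` — an 8-equal-cluster partition compared against
  random regularly sized partitions with c clusters, c swept over
  powers of two.

Also here: the problem-of-matching triplet (A, B, C) in which B moves
a fraction of each cluster to the next cluster cyclically while C
scatters the same fraction evenly over all other clusters, and full
k-ary cluster hierarchies with equal leaf blocks and nested internal
unions.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core import Clustering, ClusteringError, HierarchicalClustering, size_sequence


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _element_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"e{i:0{width}d}" for i in range(n)]


def _cluster_ids(k: int) -> list[str]:
    width = len(str(k - 1))
    return [f"c{i:0{width}d}" for i in range(k)]


def _from_labels(elements: Sequence[str], labels: np.ndarray) -> Clustering:
    """Partition from an integer label per element; empty labels dropped."""
    ids = _cluster_ids(int(labels.max()) + 1)
    clusters: dict[str, list[str]] = {}
    for e, lab in zip(elements, labels):
        clusters.setdefault(ids[lab], []).append(e)
    return Clustering(clusters, list(elements))


def equal_partition(n: int, k: int) -> Clustering:
    """k clusters of exactly n/k elements (k must divide n)."""
    if n % k != 0:
        raise ClusteringError(f"k={k} does not divide n={n}")
    elements = _element_ids(n)
    labels = np.repeat(np.arange(k), n // k)
    return _from_labels(elements, labels)


def shuffle_fraction(c: Clustering, f: float, seed=0) -> Clustering:
    """Shuffle the memberships of a fraction f of the elements.

    floor(f*N) elements are drawn uniformly without replacement and
    their cluster memberships are permuted *among themselves*, so the
    number and sizes of clusters stay exactly identical; f = 0 returns
    an equal clustering.
    """
    if not c.is_partition():
        raise ClusteringError("shuffle_fraction expects a partition")
    if not 0.0 <= f <= 1.0:
        raise ClusteringError(f"fraction {f} outside [0, 1]")
    rng = _rng(seed)
    from .classic import _labels

    labels = _labels(c).copy()
    n = len(labels)
    m = int(np.floor(f * n))
    idx = rng.choice(n, size=m, replace=False)
    labels[idx] = labels[idx][rng.permutation(m)]
    return _from_labels(c.elements, labels)


def random_regular_partition(n: int, c: int, seed=0) -> Clustering:
    """Random partition into c clusters with sizes as equal as possible."""
    if c > n:
        raise ClusteringError(f"cannot split {n} elements into {c} clusters")
    rng = _rng(seed)
    base, extra = divmod(n, c)
    sizes = np.full(c, base)
    sizes[:extra] += 1
    labels = np.repeat(np.arange(c), sizes)
    labels = labels[rng.permutation(n)]
    return _from_labels(_element_ids(n), labels)


def preferential_walk(
    c: Clustering,
    steps: int = 5_000_000,
    stride: int = 500,
    seed=0,
) -> Iterator[tuple[int, Clustering, float]]:
    """Preferential-attachment membership walk; yields snapshots.

    The initial state assigns every element uniformly at random to one
    of the input's K clusters.  Each step picks a uniform element,
    removes it from its cluster, and reassigns it to a cluster chosen
    with probability proportional to the current cluster sizes; an
    emptied cluster can never be re-entered and is dropped from the
    snapshots.  Yields (step, snapshot, size-sequence entropy) at step
    0 and every ``stride`` steps thereafter.
    """
    if not c.is_partition():
        raise ClusteringError("preferential_walk expects a partition")
    rng = _rng(seed)
    n = c.n_elements
    k = c.n_clusters
    labels = rng.integers(0, k, size=n)
    sizes = np.bincount(labels, minlength=k).astype(np.int64)

    def snapshot(step: int) -> tuple[int, Clustering, float]:
        snap = _from_labels(c.elements, labels)
        return step, snap, size_sequence(snap).entropy

    yield snapshot(0)
    picks = rng.integers(0, n, size=steps)
    draws = rng.random(size=steps)
    for step in range(1, steps + 1):
        i = picks[step - 1]
        sizes[labels[i]] -= 1
        # size-proportional choice over the current sizes
        cum = np.cumsum(sizes)
        target = int(np.searchsorted(cum, draws[step - 1] * cum[-1], side="right"))
        sizes[target] += 1
        labels[i] = target
        if step % stride == 0:
            yield snapshot(step)


def matching_triplet(n: int, k: int, f: float) -> tuple[Clustering, Clustering, Clustering]:
    """The problem-of-matching construction (A, B, C).

    A is the equal partition of n elements into k clusters.  B moves
    the first m = floor(f*n/k) elements of each cluster A_j to cluster
    A_{j+1 mod k}.  C reassigns the same m elements of each cluster
    evenly between the other k-1 clusters.  Set-matching measures see
    B and C as equally similar to A; membership-aware measures do not.
    """
    if n % k != 0:
        raise ClusteringError(f"k={k} does not divide n={n}")
    m = int(np.floor(f * n / k))
    if f > 0 and m < k - 1:
        raise ClusteringError(
            f"floor(f*n/k)={m} too small to split over {k - 1} clusters"
        )
    a = equal_partition(n, k)
    from .classic import _labels

    labels_a = _labels(a)
    labels_b = labels_a.copy()
    labels_c = labels_a.copy()
    per = n // k
    for j in range(k):
        block = np.arange(j * per, j * per + m)
        labels_b[block] = (j + 1) % k
        if m:
            offsets = 1 + (np.arange(m) % (k - 1))
            labels_c[block] = (j + offsets) % k
    return a, _from_labels(a.elements, labels_b), _from_labels(a.elements, labels_c)


def kary_hierarchy(
    branching: int = 2, depth: int = 2, leaf_size: int = 1
) -> HierarchicalClustering:
    """Full k-ary cluster hierarchy over branching^depth * leaf_size elements.

    Leaves partition the elements into equal blocks of ``leaf_size``;
    every internal cluster's members are the union of its descendants.
    Levels follow the longest-root-path rescaling, so the root sits at
    0 and the leaves at 1.
    """
    if branching < 2 or depth < 1:
        raise ClusteringError("need branching >= 2 and depth >= 1")
    n_leaves = branching**depth
    elements = _element_ids(n_leaves * leaf_size)
    clusters: dict[str, list[str]] = {}
    children: dict[str, list[str]] = {}

    def build(path: str, level: int, lo: int, hi: int) -> None:
        cid = f"c{path}" if path else "root"
        clusters[cid] = elements[lo:hi]
        if level == depth:
            children[cid] = []
            return
        kids = []
        span = (hi - lo) // branching
        for b in range(branching):
            kid_path = f"{path}.{b}" if path else str(b)
            kids.append(f"c{kid_path}")
            build(kid_path, level + 1, lo + b * span, lo + (b + 1) * span)
        children[cid] = kids

    build("", 0, 0, len(elements))
    return HierarchicalClustering(clusters, children, elements)


# ---------------------------------------------------------------------------
# Scenario runner


@dataclass
class ScenarioResult:
    """Long-format summary of a bias scenario sweep."""

    scenario: str
    parameter: str
    replicates: int
    seed: int
    rows: list[dict] = field(default_factory=list)
    # rows: {"value": parameter value, "measure": name, "mean": .., "sd": ..}

    def means(self, measure: str) -> tuple[np.ndarray, np.ndarray]:
        """(parameter values, mean similarity) series for one measure."""
        picked = [r for r in self.rows if r["measure"] == measure]
        picked.sort(key=lambda r: r["value"])
        return (
            np.array([r["value"] for r in picked]),
            np.array([r["mean"] for r in picked]),
        )

    def sds(self, measure: str) -> np.ndarray:
        picked = sorted(
            (r for r in self.rows if r["measure"] == measure),
            key=lambda r: r["value"],
        )
        return np.array([r["sd"] for r in picked])

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "scenario\tparameter\tvalue\tmeasure\tmean\tsd\t"
                "replicates\tseed\n"
            )
            for r in self.rows:
                fh.write(
                    f"{self.scenario}\t{self.parameter}\t{r['value']!r}\t"
                    f"{r['measure']}\t{r['mean']!r}\t{r['sd']!r}\t"
                    f"{self.replicates}\t{self.seed}\n"
                )


DEFAULT_MEASURES = ("elsim", "jaccard", "ari", "f", "pm", "nmi", "onmi")

SCENARIOS = ("randomized_membership", "skewed_sizes", "num_clusters")


def run_scenario(
    name: str,
    measures: Sequence[str] = DEFAULT_MEASURES,
    replicates: int = 100,
    seed: int = 0,
    scale: float = 1.0,
    n: int = 1024,
    fractions: Sequence[float] | None = None,
    steps: int | None = None,
    stride: int | None = None,
    cluster_counts: Sequence[int] | None = None,
) -> ScenarioResult:
    """Run one bias scenario and summarize each measure per sweep point.

    ``scale`` < 1 shrinks the walk length of ``skewed_sizes`` (and is
    ignored by the other scenarios, whose cost is already modest);
    replicate counts are reduced directly through ``replicates``.
    Deterministic for a given seed.
    """
    from .classic import all_measures

    registry = all_measures()
    unknown = [m for m in measures if m not in registry]
    if unknown:
        raise ClusteringError(f"unknown measure(s) {unknown}")
    funcs = {m: registry[m] for m in measures}
    root = np.random.SeedSequence(seed)
    rep_seeds = [np.random.default_rng(s) for s in root.spawn(replicates)]

    def summarize(result: ScenarioResult, value, samples: dict[str, list]):
        for m in measures:
            arr = np.array(samples[m], dtype=float)
            result.rows.append(
                {
                    "value": value,
                    "measure": m,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                }
            )

    if name == "randomized_membership":
        k = 32
        base = equal_partition(n, k)
        fr = list(fractions) if fractions is not None else [
            round(0.1 * i, 1) for i in range(11)
        ]
        result = ScenarioResult(name, "shuffled_fraction", replicates, seed)
        for f in fr:
            samples: dict[str, list] = {m: [] for m in measures}
            for rng in rep_seeds:
                shuffled = shuffle_fraction(base, f, rng)
                for m, fn in funcs.items():
                    samples[m].append(fn(base, shuffled))
            summarize(result, f, samples)
        return result

    if name == "skewed_sizes":
        k = 32
        base = equal_partition(n, k)
        total = steps if steps is not None else int(5_000_000 * scale)
        cadence = stride if stride is not None else max(1, total // 10)
        result = ScenarioResult(name, "walk_step", replicates, seed)
        per_step: dict[int, dict[str, list]] = {}
        for rng in rep_seeds:
            for step, snap, entropy in preferential_walk(
                base, steps=total, stride=cadence, seed=rng
            ):
                samples = per_step.setdefault(
                    step, {m: [] for m in (*measures, "entropy")}
                )
                samples["entropy"].append(entropy)
                for m, fn in funcs.items():
                    samples[m].append(fn(base, snap))
        for step in sorted(per_step):
            samples = per_step[step]
            summarize(result, step, samples)
            arr = np.array(samples["entropy"], dtype=float)
            result.rows.append(
                {
                    "value": step,
                    "measure": "entropy",
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                }
            )
        return result

    if name == "num_clusters":
        base = equal_partition(n, 8)
        cs = (
            list(cluster_counts)
            if cluster_counts is not None
            else [2**i for i in range(1, 11) if 2**i <= n]
        )
        result = ScenarioResult(name, "n_clusters", replicates, seed)
        for c in cs:
            samples = {m: [] for m in measures}
            for rng in rep_seeds:
                other = random_regular_partition(n, c, rng)
                for m, fn in funcs.items():
                    samples[m].append(fn(base, other))
            summarize(result, c, samples)
        return result

    raise ClusteringError(
        f"unknown scenario {name!r}; expected one of {SCENARIOS}"
    )
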