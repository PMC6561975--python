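"""Shared fixtures and random-instance helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from elcsim import Clustering, HierarchicalClustering


def random_partition(rng: np.random.Generator, n: int, k: int) -> Clustering:
    """Random partition of n elements into at most k nonempty clusters."""
    labels = rng.integers(0, k, size=n)
    clusters: dict[str, list[str]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(f"c{lab}", []).append(f"e{i}")
    return Clustering(clusters)


def random_overlapping(
    rng: np.random.Generator, n: int, k: int, p_extra: float = 0.3
) -> Clustering:
    """Random cover: a partition plus extra memberships with prob p_extra."""
    base = random_partition(rng, n, k)
    clusters = {cid: set(mem) for cid, mem in base.clusters.items()}
    ids = list(clusters)
    for i in range(n):
        if len(ids) > 1 and rng.random() < p_extra:
            clusters[ids[rng.integers(len(ids))]].add(f"e{i}")
    return Clustering(clusters)


def random_hierarchy(rng: np.random.Generator, n: int) -> HierarchicalClustering:
    """Random binary cluster hierarchy over n elements (nested unions)."""
    elements = [f"e{i}" for i in range(n)]
    perm = rng.permutation(n)
    clusters: dict[str, list[str]] = {}
    children: dict[str, list[str]] = {}
    counter = [0]

    def split(idx: np.ndarray) -> str:
        cid = f"h{counter[0]}"
        counter[0] += 1
        clusters[cid] = [elements[i] for i in idx]
        if len(idx) > 2 and rng.random() < 0.8:
            cut = rng.integers(1, len(idx))
            children[cid] = [split(idx[:cut]), split(idx[cut:])]
        else:
            children[cid] = []
        return cid

    split(perm)
    return HierarchicalClustering(clusters, children, elements)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def nine_one_cluster() -> Clustering:
    return Clustering({"all": [f"e{i}" for i in range(9)]})


@pytest.fixture
def nine_singletons() -> Clustering:
    return Clustering({f"s{i}": [f"e{i}"] for i in range(9)})
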