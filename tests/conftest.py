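import math

import networkx as nx
import numpy as np
import pytest
from skbio import DistanceMatrix

from siroclass.alignment import ScoringScheme
from siroclass.feature_detect import default_profile


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def blosum():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def identity():
    return ScoringScheme.identity()


def brute_force_global_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Exhaustive enumeration of all global alignments (oracle, len <= ~8).

    Scores gap runs as gap_open + (L-1)*gap_extend, independently of the
    dynamic program it is used to check.
    """
    best = -math.inf
    go, ge = scheme.gap_open, scheme.gap_extend

    def rec(i, j, prev, sc):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, sc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", sc + scheme.score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "D", sc + (ge if prev == "D" else go))
        if j < len(b):
            rec(i, j + 1, "I", sc + (ge if prev == "I" else go))

    rec(0, 0, None, 0.0)
    return best


def random_additive_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """Distance matrix of a random edge-weighted binary tree (oracle input).

    Built by sequential edge subdivision, so the matrix is additive by
    construction; pairwise distances are exact path lengths on the tree.
    """
    labels = [f"T{i}" for i in range(n)]
    g = nx.Graph()
    g.add_edge("T0", "T1", weight=float(rng.uniform(0.1, 2.0)))
    nid = 0
    for k in range(2, n):
        edges = list(g.edges(data=True))
        u, v, d = edges[rng.integers(len(edges))]
        w = d["weight"]
        g.remove_edge(u, v)
        mid = f"X{nid}"
        nid += 1
        split = float(rng.uniform(0.1, 0.9)) * w
        g.add_edge(u, mid, weight=split)
        g.add_edge(mid, v, weight=w - split)
        g.add_edge(mid, labels[k], weight=float(rng.uniform(0.05, 1.0)))
    d = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n):
        for j in range(n):
            d[i, j] = paths[labels[i]][labels[j]]
    return DistanceMatrix(0.5 * (d + d.T), ids=labels)
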