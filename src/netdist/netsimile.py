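"""NetSimile: feature-based graph comparison.

Seven local/egonet features are computed per vertex, aggregated into a
35-entry signature vector (mean, median, standard deviation, skewness,
excess kurtosis of each feature), and signatures are compared with the
Canberra distance.  The whole pipeline is permutation-invariant and needs no
node correspondence, so graphs of different sizes can be compared.

Graphs are treated as unweighted: any positive weight counts as an edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.stats

from .errors import GraphValidationError
from .graph_core import Graph

FEATURE_NAMES: Tuple[str, ...] = (
    "degree",
    "clustering_coefficient",
    "mean_neighbor_degree",
    "mean_neighbor_clustering",
    "egonet_edges",
    "egonet_outgoing_edges",
    "egonet_neighbors",
)

STATISTIC_NAMES: Tuple[str, ...] = (
    "mean",
    "median",
    "std",
    "skewness",
    "kurtosis",
)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-vertex feature matrix, rows = 7 features, columns = vertices."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != len(FEATURE_NAMES):
            raise GraphValidationError(
                f"feature matrix must have {len(FEATURE_NAMES)} rows"
            )
        if not np.all(np.isfinite(v)):
            raise GraphValidationError("feature matrix contains non-finite entries")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SignatureVector:
    """35-entry graph signature: 5 statistics of each of 7 features."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(FEATURE_NAMES) * len(STATISTIC_NAMES),):
            raise GraphValidationError("signature must have 35 entries")
        if not np.all(np.isfinite(v)):
            raise GraphValidationError("signature contains non-finite entries")
        object.__setattr__(self, "values", v)

    def labels(self) -> Tuple[str, ...]:
        return tuple(
            f"{f}_{s}" for f in FEATURE_NAMES for s in STATISTIC_NAMES
        )


def node_features(g: Graph) -> FeatureMatrix:
    """The 7 NetSimile features for every vertex.

    Per vertex i: degree; clustering coefficient; mean neighbor degree; mean
    neighbor clustering coefficient; number of edges in i's egonet (i, its
    neighbors, and all edges among them); number of edges leaving the egonet;
    number of distinct external neighbors of the egonet.  Degenerate cases
    (isolated vertices, degree-1 clustering) map to 0.
    """
    n = g.n
    adj = [set() for _ in range(n)]
    for (i, j) in g.weights:
        adj[i].add(j)
        adj[j].add(i)

    deg = np.array([len(a) for a in adj], dtype=float)

    # clustering coefficient: triangles / possible pairs of neighbors
    clus = np.zeros(n)
    for i in range(n):
        d = len(adj[i])
        if d < 2:
            continue
        links = 0
        nbrs = adj[i]
        for u in nbrs:
            links += len(adj[u] & nbrs)
        links //= 2
        clus[i] = 2.0 * links / (d * (d - 1))

    feats = np.zeros((len(FEATURE_NAMES), n))
    feats[0] = deg
    feats[1] = clus
    for i in range(n):
        nbrs = adj[i]
        if nbrs:
            # sorted accumulation keeps the features exactly permutation-
            # equivariant (float addition is not associative)
            feats[2, i] = float(np.mean(sorted(deg[u] for u in nbrs)))
            feats[3, i] = float(np.mean(sorted(clus[u] for u in nbrs)))
        ego = nbrs | {i}
        inside = 0
        outgoing = 0
        external = set()
        for u in ego:
            for v in adj[u]:
                if v in ego:
                    inside += 1
                else:
                    outgoing += 1
                    external.add(v)
        feats[4, i] = inside // 2
        feats[5, i] = outgoing
        feats[6, i] = len(external)
    return FeatureMatrix(feats)


def _aggregate(row: np.ndarray) -> np.ndarray:
    row = np.sort(row)  # order-free statistics, exactly permutation-invariant
    std = float(np.std(row, ddof=1)) if len(row) > 1 else 0.0
    if std > 0:
        skew = float(scipy.stats.skew(row))
        kurt = float(scipy.stats.kurtosis(row))  # excess (Fisher)
    else:
        skew = kurt = 0.0  # constant feature, e.g. on regular graphs
    return np.array([float(np.mean(row)), float(np.median(row)), std, skew, kurt])


def signature(g: Graph) -> SignatureVector:
    """Aggregate the feature matrix into the 35-entry signature vector."""
    if g.n < 1:
        raise GraphValidationError("signature requires at least one vertex")
    feats = node_features(g).values
    return SignatureVector(np.concatenate([_aggregate(row) for row in feats]))


def netsimile_distance(g: Graph, h: Graph) -> float:
    """Canberra distance between the signature vectors of two graphs.

    Terms with ``|s| + |s'| = 0`` contribute 0, so identical graphs (and
    permutations of one graph) are at distance exactly 0.
    """
    a = signature(g).values
    b = signature(h).values
    denom = np.abs(a) + np.abs(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, np.abs(a - b) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.sum())
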