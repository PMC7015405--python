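"""Graph data model, matrix representations, file I/O, and connectome construction.

Graphs are simple (no self-loops, no parallel edges), undirected, with
strictly positive edge weights and 0-based vertex indices.  The three matrix
representations are the adjacency matrix ``A``, the combinatorial Laplacian
``L = D - A`` and the normalized Laplacian ``D^{-1/2} L D^{-1/2}`` (with the
convention that ``D^{-1/2}`` is 0 on zero-degree vertices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import GraphValidationError

Edge = Tuple[int, int]

MATRIX_KINDS = ("adjacency", "laplacian", "normalized_laplacian")


def _canon(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Graph:
    """An undirected weighted simple graph on vertices ``0..n-1``.

    Parameters
    ----------
    n
        Number of vertices (non-negative).
    weights
        Mapping from canonical edges ``(i, j)`` with ``i < j`` to strictly
        positive weights.  Unweighted graphs use weight 1.0.
    """

    n: int
    weights: Mapping[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise GraphValidationError(f"vertex count must be >= 0, got {self.n}")
        canon: Dict[Edge, float] = {}
        for (i, j), w in dict(self.weights).items():
            if i == j:
                raise GraphValidationError(f"self-loop on vertex {i} is not allowed")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise GraphValidationError(
                    f"edge ({i}, {j}) out of range for n={self.n}"
                )
            w = float(w)
            if not w > 0:
                raise GraphValidationError(
                    f"edge ({i}, {j}) has non-positive weight {w}"
                )
            e = _canon(i, j)
            if e in canon and canon[e] != w:
                raise GraphValidationError(
                    f"duplicate edge {e} with conflicting weights {canon[e]} and {w}"
                )
            canon[e] = w
        object.__setattr__(self, "weights", canon)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: Iterable[Edge],
        weights: Iterable[float] | None = None,
    ) -> "Graph":
        edges = list(edges)
        if weights is None:
            weights = [1.0] * len(edges)
        return cls(n, dict(zip((_canon(*e) for e in edges), map(float, weights))))

    @classmethod
    def from_adjacency(cls, a: np.ndarray | sp.spmatrix, tol: float = 1e-10) -> "Graph":
        """Build a graph from a symmetric non-negative adjacency matrix."""
        a = sp.coo_matrix(a)
        if a.shape[0] != a.shape[1]:
            raise GraphValidationError("adjacency matrix must be square")
        dense_check = abs(a - a.T)
        if dense_check.nnz and dense_check.max() > tol:
            raise GraphValidationError("adjacency matrix must be symmetric")
        w: Dict[Edge, float] = {}
        for i, j, v in zip(a.row, a.col, a.data):
            if v == 0:
                continue
            if i == j:
                raise GraphValidationError(f"nonzero diagonal entry at {i}")
            w[_canon(int(i), int(j))] = float(v)
        return cls(a.shape[0], w)

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        import networkx as nx

        if g.is_directed() or g.is_multigraph():
            raise GraphValidationError("only simple undirected graphs are supported")
        nodes = list(g.nodes())
        idx = {v: i for i, v in enumerate(nodes)}
        w = {
            _canon(idx[u], idx[v]): float(d.get("weight", 1.0))
            for u, v, d in g.edges(data=True)
        }
        return cls(len(nodes), w)

    # -- views ---------------------------------------------------------------

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.weights)

    @property
    def edges(self) -> Tuple[Edge, ...]:
        return tuple(sorted(self.weights))

    def weight(self, i: int, j: int) -> float:
        return self.weights.get(_canon(i, j), 0.0)

    def is_unweighted(self) -> bool:
        return all(w == 1.0 for w in self.weights.values())

    def to_adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n))
        for (i, j), w in self.weights.items():
            a[i, j] = a[j, i] = w
        return a

    def to_sparse(self) -> sp.csr_matrix:
        if not self.weights:
            return sp.csr_matrix((self.n, self.n))
        rows, cols, vals = [], [], []
        for (i, j), w in self.weights.items():
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_weighted_edges_from((i, j, w) for (i, j), w in self.weights.items())
        return g

    def neighbors(self, i: int) -> Tuple[int, ...]:
        out = []
        for (u, v) in self.weights:
            if u == i:
                out.append(v)
            elif v == i:
                out.append(u)
        return tuple(sorted(out))


@dataclass(frozen=True)
class MatrixRepresentation:
    """A symmetric matrix representation of a graph."""

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise GraphValidationError(
                f"unknown matrix representation {self.kind!r}; "
                f"expected one of {MATRIX_KINDS}"
            )
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise GraphValidationError("matrix representation must be square")
        if v.size and np.max(np.abs(v - v.T)) > 1e-10:
            raise GraphValidationError("matrix representation must be symmetric")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CorrelationMatrix:
    """A symmetric correlation matrix with unit diagonal and entries in [-1, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise GraphValidationError("correlation matrix must be square")
        if v.size:
            if np.max(np.abs(v - v.T)) > 1e-10:
                raise GraphValidationError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(v), 1.0):
                raise GraphValidationError("correlation matrix diagonal must be 1")
            if np.max(np.abs(v)) > 1.0 + 1e-10:
                raise GraphValidationError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


# -- basic queries ------------------------------------------------------------


def degrees(g: Graph) -> np.ndarray:
    """Weighted degree of each vertex; isolated vertices get 0."""
    d = np.zeros(g.n)
    for (i, j), w in g.weights.items():
        d[i] += w
        d[j] += w
    return d


def volume(g: Graph) -> float:
    """Total edge weight (= number of edges for unweighted graphs)."""
    return float(sum(g.weights.values()))


def connected_components(g: Graph) -> Tuple[int, np.ndarray]:
    """Number of connected components and a vertex -> component label array."""
    if g.n == 0:
        return 0, np.zeros(0, dtype=int)
    count, labels = sp.csgraph.connected_components(g.to_sparse(), directed=False)
    return int(count), labels


def is_connected(g: Graph) -> bool:
    return g.n <= 1 or connected_components(g)[0] == 1


def matrix_representation(g: Graph, kind: str) -> MatrixRepresentation:
    """Adjacency, combinatorial Laplacian, or normalized Laplacian of ``g``.

    The normalized Laplacian uses ``D^{-1/2} L D^{-1/2}`` with
    ``D^{-1/2}_{ii} = 0`` whenever vertex ``i`` is isolated, so isolated
    vertices contribute an all-zero row and column.
    """
    if kind not in MATRIX_KINDS:
        raise GraphValidationError(
            f"unknown matrix representation {kind!r}; expected one of {MATRIX_KINDS}"
        )
    a = g.to_adjacency()
    if kind == "adjacency":
        return MatrixRepresentation(kind, a)
    d = degrees(g)
    lap = np.diag(d) - a
    if kind == "laplacian":
        return MatrixRepresentation(kind, lap)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    nlap = dinv_sqrt[:, None] * lap * dinv_sqrt[None, :]
    nlap = (nlap + nlap.T) / 2.0  # kill round-off asymmetry
    return MatrixRepresentation(kind, nlap)


def permute(g: Graph, perm: Sequence[int]) -> Graph:
    """Relabel vertices: vertex ``i`` of ``g`` becomes ``perm[i]``.

    The adjacency of the result equals ``P^T A P`` for the permutation matrix
    ``P`` with ``P[perm[i], i] = 1``.
    """
    perm = list(perm)
    if sorted(perm) != list(range(g.n)):
        raise GraphValidationError("perm must be a bijection on 0..n-1")
    w = {_canon(perm[i], perm[j]): wt for (i, j), wt in g.weights.items()}
    return Graph(g.n, w)


# -- file I/O -----------------------------------------------------------------


def write_edge_list(g: Graph, path) -> None:
    """Write a graph as whitespace-separated ``i j w`` lines (0-based)."""
    with open(path, "w") as fh:
        fh.write(f"# netdist edge list, n={g.n}\n")
        for (i, j) in g.edges:
            w = g.weights[(i, j)]
            if w == 1.0:
                fh.write(f"{i} {j}\n")
            else:
                fh.write(f"{i} {j} {w!r}\n")


def read_edge_list(path, n: int | None = None) -> Graph:
    """Read a graph from an edge-list text file.

    Lines are ``i j [w]`` with 0-based integer vertices and an optional
    positive weight; ``#`` starts a comment.  A header comment ``n=<int>``
    (written by :func:`write_edge_list`) fixes the vertex count; otherwise it
    is ``max index + 1`` or the explicit ``n`` argument.
    """
    weights: Dict[Edge, float] = {}
    max_idx = -1
    header_n = n
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if "#" in raw and header_n is None and "n=" in raw:
                comment = raw.split("#", 1)[1]
                for tok in comment.replace(",", " ").split():
                    if tok.startswith("n="):
                        try:
                            header_n = int(tok[2:])
                        except ValueError:
                            pass
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphValidationError(
                    f"{path}:{lineno}: expected 'i j [w]', got {raw.strip()!r}"
                )
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphValidationError(
                    f"{path}:{lineno}: non-integer vertex index"
                ) from exc
            if i == j:
                raise GraphValidationError(f"{path}:{lineno}: self-loop on vertex {i}")
            if i < 0 or j < 0:
                raise GraphValidationError(f"{path}:{lineno}: negative vertex index")
            w = 1.0
            if len(parts) == 3:
                w = float(parts[2])
                if not w > 0:
                    raise GraphValidationError(
                        f"{path}:{lineno}: non-positive weight {w}"
                    )
            e = _canon(i, j)
            if e in weights and weights[e] != w:
                raise GraphValidationError(
                    f"{path}:{lineno}: duplicate edge {e} with conflicting weight"
                )
            weights[e] = w
            max_idx = max(max_idx, i, j)
    n_final = header_n if header_n is not None else max_idx + 1
    if max_idx >= n_final:
        raise GraphValidationError(
            f"{path}: vertex index {max_idx} out of range for n={n_final}"
        )
    return Graph(n_final, weights)


def write_adjacency(g: Graph, path) -> None:
    """Write the adjacency matrix in Matrix Market symmetric coordinate format."""
    scipy.io.mmwrite(
        path,
        sp.coo_matrix(np.tril(g.to_adjacency())),
        symmetry="symmetric",
        comment=f"netdist adjacency, n={g.n}",
    )


def read_adjacency(path) -> Graph:
    """Read a graph from a Matrix Market adjacency file."""
    a = scipy.io.mmread(path)
    return Graph.from_adjacency(a)


# -- connectome construction ---------------------------------------------------


def threshold_correlation_matrix(
    c: CorrelationMatrix, threshold: float, mode: str = "weighted"
) -> Graph:
    """Build a connectome graph from a correlation matrix.

    An edge joins regions ``u != v`` whenever ``|rho(u, v)| >= threshold``;
    low correlations are dropped as likely spurious.  ``mode="weighted"``
    assigns weight ``|rho(u, v)|``, ``mode="binary"`` assigns weight 1.  The
    diagonal is excluded (no self-loops); isolated regions are retained so the
    vertex set matches the atlas.
    """
    if not 0.0 <= threshold <= 1.0:
        raise GraphValidationError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in ("weighted", "binary"):
        raise GraphValidationError(f"mode must be 'weighted' or 'binary', got {mode!r}")
    w: Dict[Edge, float] = {}
    vals = c.values
    for i in range(c.n):
        for j in range(i + 1, c.n):
            r = abs(vals[i, j])
            if r >= threshold and r > 0:
                w[(i, j)] = 1.0 if mode == "binary" else r
    return Graph(c.n, w)
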