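"""Matrix distances: edit, resistance-perturbation, and DeltaCon.

These distances compare node-affinity matrices entrywise and therefore
require node correspondence: vertex ``i`` of one graph must mean the same
entity as vertex ``i`` of the other.

The effective resistance ``R(u, v)`` treats each edge as a resistor of
conductance equal to its weight; it is computed from the Moore-Penrose
pseudoinverse of the combinatorial Laplacian and is a metric on the vertices
of a connected graph.  The renormalized variant ``rho = R / (1 + R)`` is
bounded in [0, 1] and extends across components (``rho = 1`` for vertices in
different components, the ``R -> infinity`` limit).

DeltaCon compares fast-belief-propagation affinity matrices
``S = [I + eps^2 D - eps A]^{-1}`` via the Matusita difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.linalg

from .errors import (
    DisconnectedGraphError,
    GraphValidationError,
    SizeMismatchError,
)
from .graph_core import Graph, connected_components, degrees, is_connected

AFFINITY_KINDS = ("adjacency", "resistance", "renormalized_resistance", "fbp")

#: exact O(n^2)-and-worse algorithms only; warn above this size
SIZE_GUARD = 5000

_EIG_DROP = 1e-10


@dataclass(frozen=True)
class AffinityMatrix:
    """A symmetric matrix of pairwise node affinities."""

    kind: str
    values: np.ndarray
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in AFFINITY_KINDS:
            raise GraphValidationError(f"unknown affinity kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "params", dict(self.params))


def _check_same_size(g: Graph, h: Graph, name: str) -> None:
    if g.n != h.n:
        raise SizeMismatchError(
            f"{name} requires node correspondence: graphs have "
            f"{g.n} and {h.n} vertices"
        )


def _size_guard(g: Graph) -> None:
    if g.n > SIZE_GUARD:
        warnings.warn(
            f"exact matrix distance on n={g.n} > {SIZE_GUARD} vertices; "
            "this is O(n^2) memory and O(n^3) time",
            stacklevel=3,
        )


def edit_distance(g: Graph, h: Graph) -> float:
    """Entrywise l1 norm of the difference of adjacency matrices.

    Each discrepant undirected edge is counted twice (once per ordered
    pair); for unweighted graphs the value is twice the size of the
    symmetric difference of the edge sets.
    """
    _check_same_size(g, h, "edit distance")
    total = 0.0
    for e in set(g.weights) | set(h.weights):
        total += abs(g.weights.get(e, 0.0) - h.weights.get(e, 0.0))
    return 2.0 * total


def _laplacian_pinv(g: Graph) -> np.ndarray:
    """Pseudoinverse of the combinatorial Laplacian via eigendecomposition,
    dropping eigenvalues below 1e-10 * lambda_max."""
    lap = np.diag(degrees(g)) - g.to_adjacency()
    vals, vecs = np.linalg.eigh(lap)
    cut = _EIG_DROP * max(vals.max(initial=0.0), 1.0)
    inv = np.where(vals > cut, 1.0 / np.where(vals > cut, vals, 1.0), 0.0)
    return (vecs * inv) @ vecs.T


def _resistance_from_pinv(lp: np.ndarray) -> np.ndarray:
    d = np.diag(lp)
    r = d[:, None] + d[None, :] - 2.0 * lp
    np.fill_diagonal(r, 0.0)
    return np.maximum(r, 0.0)


def resistance_matrix(g: Graph) -> AffinityMatrix:
    """Effective-resistance matrix of a connected graph."""
    if not is_connected(g):
        raise DisconnectedGraphError(
            "effective resistance is undefined for disconnected graphs; "
            "use renormalized_resistance_matrix instead"
        )
    _size_guard(g)
    return AffinityMatrix("resistance", _resistance_from_pinv(_laplacian_pinv(g)))


def renormalized_resistance_matrix(g: Graph) -> AffinityMatrix:
    """Bounded resistance affinity ``rho = R / (1 + R)``, defined on any graph.

    Within a connected component this is a strictly monotone transform of the
    effective resistance; vertices in different components get ``rho = 1``.
    """
    _size_guard(g)
    n = g.n
    rho = np.ones((n, n))
    np.fill_diagonal(rho, 0.0)
    ncomp, labels = connected_components(g)
    for c in range(ncomp):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            continue
        sub_map = {int(v): i for i, v in enumerate(idx)}
        sub = Graph(
            len(idx),
            {
                (sub_map[i], sub_map[j]): w
                for (i, j), w in g.weights.items()
                if labels[i] == c
            },
        )
        r = _resistance_from_pinv(_laplacian_pinv(sub))
        rho[np.ix_(idx, idx)] = r / (1.0 + r)
    np.fill_diagonal(rho, 0.0)
    return AffinityMatrix("renormalized_resistance", rho)


def resistance_distance(g: Graph, h: Graph, renormalized: bool = False) -> float:
    """Resistance-perturbation distance: entrywise l1 norm of ``R - R'``.

    With ``renormalized=True`` the bounded affinity ``rho = R/(1+R)`` is
    compared instead, which accepts disconnected inputs.
    """
    _check_same_size(g, h, "resistance distance")
    if renormalized:
        mg = renormalized_resistance_matrix(g).values
        mh = renormalized_resistance_matrix(h).values
    else:
        mg = resistance_matrix(g).values
        mh = resistance_matrix(h).values
    return float(np.abs(mg - mh).sum())


def default_epsilon(g: Graph, h: Graph | None = None) -> float:
    """DeltaCon default ``eps = 1 / (1 + max degree)`` over both graphs."""
    dmax = degrees(g).max(initial=0.0)
    if h is not None:
        dmax = max(dmax, degrees(h).max(initial=0.0))
    return 1.0 / (1.0 + dmax)


def fbp_matrix(g: Graph, epsilon: float) -> AffinityMatrix:
    """Fast-belief-propagation affinity matrix ``[I + eps^2 D - eps A]^{-1}``.

    Neighbors at path distance k contribute at order ``eps^k``:
    ``S = I + eps A + eps^2 (A^2 - D) + O(eps^3)``.
    """
    if epsilon < 0:
        raise GraphValidationError(f"epsilon must be >= 0, got {epsilon}")
    _size_guard(g)
    a = g.to_adjacency()
    m = np.eye(g.n) + epsilon**2 * np.diag(degrees(g)) - epsilon * a
    try:
        s = scipy.linalg.solve(m, np.eye(g.n), assume_a="sym")
    except np.linalg.LinAlgError as exc:
        raise GraphValidationError(
            f"fbp system is singular at epsilon={epsilon}; reduce epsilon"
        ) from exc
    s = (s + s.T) / 2.0
    return AffinityMatrix("fbp", s, {"epsilon": float(epsilon)})


def deltacon(
    g: Graph,
    h: Graph,
    epsilon: float | None = None,
    variant: str = "matusita",
) -> float:
    """DeltaCon distance between fast-belief-propagation matrices.

    ``variant="matusita"`` (default) is
    ``sqrt( sum_ij (sqrt(S_ij) - sqrt(S'_ij))^2 )`` with negative entries
    clamped to 0 before the square root; ``variant="frobenius"`` compares the
    raw entries, ``sum_ij (S_ij - S'_ij)^2``.
    """
    _check_same_size(g, h, "DeltaCon")
    if epsilon is None:
        epsilon = default_epsilon(g, h)
    sg = fbp_matrix(g, epsilon).values
    sh = fbp_matrix(h, epsilon).values
    if variant == "matusita":
        diff = np.sqrt(np.maximum(sg, 0.0)) - np.sqrt(np.maximum(sh, 0.0))
        return float(np.sqrt(np.sum(diff**2)))
    if variant == "frobenius":
        return float(np.sum((sg - sh) ** 2))
    raise GraphValidationError(f"unknown DeltaCon variant {variant!r}")


def rp_single_edge_closed_form(
    g: Graph, i0: int, j0: int, delta_w: float
) -> float:
    """Closed-form resistance-perturbation distance for a single-edge change.

    For a perturbation ``delta_w`` of the weight of edge ``(i0, j0)`` of a
    connected graph the entrywise-l1 resistance distance between ``g`` and
    the perturbed graph is::

        2 n * |dw| / (1 + dw * R_{i0 j0}) * sum_{k>=2} (phi_k(i0) - phi_k(j0))^2 / lambda_k^2

    where ``lambda_k, phi_k`` are the eigenpairs of the **combinatorial**
    Laplacian in ascending order.  This follows from the rank-one
    (Sherman-Morrison) update of the Laplacian pseudoinverse and agrees with
    direct recomputation of both resistance matrices.
    """
    if not is_connected(g):
        raise DisconnectedGraphError("closed form requires a connected graph")
    if not (0 <= i0 < g.n and 0 <= j0 < g.n) or i0 == j0:
        raise GraphValidationError(f"invalid edge ({i0}, {j0})")
    w0 = g.weight(i0, j0)
    if w0 + delta_w < -1e-12:
        raise GraphValidationError(
            f"perturbation gives negative weight {w0 + delta_w} on ({i0}, {j0})"
        )
    if delta_w == 0:
        return 0.0
    lap = np.diag(degrees(g)) - g.to_adjacency()
    vals, vecs = np.linalg.eigh(lap)
    cut = _EIG_DROP * max(vals.max(initial=0.0), 1.0)
    diffs = vecs[i0, :] - vecs[j0, :]
    keep = vals > cut
    r0 = float(np.sum(diffs[keep] ** 2 / vals[keep]))
    denom = 1.0 + delta_w * r0
    if denom <= 1e-12:
        # removing a bridge entirely: the perturbed graph is disconnected
        warnings.warn(
            "perturbation disconnects the graph; falling back to direct "
            "recomputation",
            stacklevel=2,
        )
        return _rp_direct(g, i0, j0, delta_w)
    response = float(np.sum(diffs[keep] ** 2 / vals[keep] ** 2))
    return 2.0 * g.n * abs(delta_w) / denom * response


def _rp_direct(g: Graph, i0: int, j0: int, delta_w: float) -> float:
    """Direct-recomputation oracle for the single-edge perturbation."""
    from .graph_core import _canon

    w = dict(g.weights)
    e = _canon(i0, j0)
    new_w = w.get(e, 0.0) + delta_w
    if new_w > 1e-12:
        w[e] = new_w
    else:
        w.pop(e, None)
    return resistance_distance(g, Graph(g.n, w))
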