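"""Eigenvalue computation and spectral distances.

Ordering conventions: adjacency spectra are sorted descending (the largest
eigenvalues carry coarse structure such as communities), Laplacian spectra
ascending (the smallest eigenvalues do).  Truncated spectral distances
compare the first ``k`` eigenvalues under the matrix's own ordering, so the
adjacency distance compares the k largest and the Laplacian distances the k
smallest eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import scipy.sparse.linalg

from .errors import GraphValidationError, SizeMismatchError
from .graph_core import MATRIX_KINDS, Graph, degrees, matrix_representation

#: above this size the dense symmetric eigensolver is replaced by an
#: iterative sparse solver, which then requires an explicit k
DENSE_LIMIT = 2000

_SOLVER_TOL = 1e-8


@dataclass(frozen=True)
class Spectrum:
    """An ordered eigenvalue sequence of one matrix representation."""

    kind: str
    values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.kind not in MATRIX_KINDS:
            raise GraphValidationError(f"unknown spectrum kind {self.kind!r}")
        if len(v) != self.k:
            raise GraphValidationError("spectrum length must equal k")

    @property
    def ordering(self) -> str:
        return "descending" if self.kind == "adjacency" else "ascending"


def compute_spectrum(g: Graph, kind: str, k: int | None = None) -> Spectrum:
    """Eigenvalues of a matrix representation of ``g`` under its ordering.

    ``k`` truncates: the k largest eigenvalues for the adjacency matrix, the
    k smallest for either Laplacian.  Omitted ``k`` means the full spectrum.
    """
    if kind not in MATRIX_KINDS:
        raise GraphValidationError(f"unknown spectrum kind {kind!r}")
    n = g.n
    if k is None:
        k = n
    if not 1 <= k <= n:
        raise GraphValidationError(f"k must satisfy 1 <= k <= n={n}, got {k}")
    descending = kind == "adjacency"
    if n <= DENSE_LIMIT or k >= n - 1:
        vals = np.linalg.eigvalsh(matrix_representation(g, kind).values)
        # eigvalsh returns ascending order
        vals = vals[::-1][:k] if descending else vals[:k]
    else:
        m = g.to_sparse().astype(float)
        if kind != "adjacency":
            d = scipy.sparse.diags(degrees(g))
            m = d - m
            if kind == "normalized_laplacian":
                dd = degrees(g)
                inv = np.where(dd > 0, 1.0 / np.sqrt(np.where(dd > 0, dd, 1.0)), 0.0)
                s = scipy.sparse.diags(inv)
                m = s @ m @ s
        v0 = np.random.default_rng(0).standard_normal(n)  # deterministic start
        which = "LA" if descending else "SA"
        vals = scipy.sparse.linalg.eigsh(
            m, k=k, which=which, tol=_SOLVER_TOL, v0=v0, return_eigenvectors=False
        )
        vals = np.sort(vals)
        vals = vals[::-1] if descending else vals
    return Spectrum(kind, np.array(vals), k)


def _lp(diff: np.ndarray, p: float) -> float:
    diff = np.abs(diff)
    if p == 0:
        return float(np.count_nonzero(diff > _SOLVER_TOL))
    if np.isinf(p):
        return float(diff.max(initial=0.0))
    if p < 1:
        warnings.warn(
            f"l_{p} with p < 1 is not a true metric (triangle inequality fails)",
            stacklevel=3,
        )
    return float(np.sum(diff**p) ** (1.0 / p))


def spectral_distance(
    g: Graph,
    h: Graph,
    kind: str,
    k: int | None = None,
    p: float = 2.0,
) -> float:
    """l_p distance between the (truncated) spectra of two graphs.

    Permutation-invariant and correspondence-free.  Graphs of different sizes
    can only be compared with an explicit truncation ``k <= min(n_g, n_h)``;
    no zero-padding convention is imposed.
    """
    if g.n != h.n and k is None:
        raise SizeMismatchError(
            f"graphs have different sizes ({g.n} vs {h.n}); "
            "supply k <= min(n, n') to compare truncated spectra"
        )
    if k is not None and k > min(g.n, h.n):
        raise GraphValidationError(
            f"k={k} exceeds the smaller graph size {min(g.n, h.n)}"
        )
    sg = compute_spectrum(g, kind, k)
    sh = compute_spectrum(h, kind, k)
    return _lp(sg.values - sh.values, p)


def spectral_density(
    spectra: Iterable[Spectrum], bins: int | Sequence[float] = 50
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized histogram (area 1) of pooled eigenvalues.

    All spectra must share the same matrix kind.  Returns
    ``(densities, bin_edges)`` as from :func:`numpy.histogram`.
    """
    spectra = list(spectra)
    if not spectra:
        raise GraphValidationError("spectral_density requires at least one spectrum")
    kinds = {s.kind for s in spectra}
    if len(kinds) > 1:
        raise GraphValidationError(f"mixed spectrum kinds {sorted(kinds)}")
    pooled = np.concatenate([s.values for s in spectra])
    return np.histogram(pooled, bins=bins, density=True)
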