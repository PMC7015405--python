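"""The contrast-statistic evaluation protocol.

To compare a null graph population G0 with an alternative G1 through the
lens of a distance d, sample D0 = d(G0, G0') with both draws from the null
and D1 = d(G0, G1) across populations, then studentize:

    contrast = (D1 - mean(D0)) / std(D0)

A contrast well separated from zero means the distance tells the two
populations apart relative to the null's own variability.  The statistic is
invariant under any global rescaling d -> c d.

Also provided: paired k-sweeps for spectral distances, temporal difference
series for dynamic graphs (change-point detection), and the edgewise
population contrast for correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np

from . import matrix_distances, netsimile, spectra
from .ensembles import EnsembleSpec, sample
from .errors import DegenerateStatisticError, GraphValidationError, SizeMismatchError
from .graph_core import CorrelationMatrix, Graph

QUANTILES = (5, 25, 50, 75, 95)

DistanceFn = Callable[[Graph, Graph], float]

#: distances that require node correspondence (same vertex set, same labels)
CORRESPONDENCE_DISTANCES = frozenset(
    {"edit", "resistance", "resistance_renormalized", "deltacon"}
)

DISTANCE_NAMES = (
    "edit",
    "resistance",
    "resistance_renormalized",
    "deltacon",
    "netsimile",
    "spectral_adjacency",
    "spectral_laplacian",
    "spectral_nlaplacian",
)

_SPECTRAL_KINDS = {
    "spectral_adjacency": "adjacency",
    "spectral_laplacian": "laplacian",
    "spectral_nlaplacian": "normalized_laplacian",
}


def get_distance(name: str, **params) -> DistanceFn:
    """Look up a distance by name, binding its parameters.

    Spectral distances accept ``k`` (truncation) and ``p`` (norm order);
    DeltaCon accepts ``epsilon`` and ``variant``.
    """
    if name == "edit":
        return matrix_distances.edit_distance
    if name == "resistance":
        return lambda g, h: matrix_distances.resistance_distance(g, h)
    if name == "resistance_renormalized":
        return lambda g, h: matrix_distances.resistance_distance(
            g, h, renormalized=True
        )
    if name == "deltacon":
        eps = params.get("epsilon")
        variant = params.get("variant", "matusita")
        return lambda g, h: matrix_distances.deltacon(
            g, h, epsilon=eps, variant=variant
        )
    if name == "netsimile":
        return netsimile.netsimile_distance
    if name in _SPECTRAL_KINDS:
        kind = _SPECTRAL_KINDS[name]
        k = params.get("k")
        p = params.get("p", 2.0)
        return lambda g, h: spectra.spectral_distance(g, h, kind, k=k, p=p)
    raise GraphValidationError(
        f"unknown distance {name!r}; expected one of {DISTANCE_NAMES}"
    )


@dataclass(frozen=True)
class ContrastSummary:
    """Samples of D0 and D1 with the studentized contrast and its quantiles."""

    d0_samples: np.ndarray
    d1_samples: np.ndarray
    mu0: float
    sigma0: float
    contrast_samples: np.ndarray
    quantiles: Dict[int, float]

    @classmethod
    def from_samples(
        cls, d0: Sequence[float], d1: Sequence[float]
    ) -> "ContrastSummary":
        d0 = np.asarray(d0, dtype=float)
        d1 = np.asarray(d1, dtype=float)
        mu0 = float(np.mean(d0))
        sigma0 = float(np.std(d0, ddof=1))
        if sigma0 == 0:
            raise DegenerateStatisticError(
                "null distance samples have zero variance (e.g. a deterministic "
                "null ensemble); the contrast is undefined"
            )
        contrast = (d1 - mu0) / sigma0
        q = {p: float(np.percentile(contrast, p)) for p in QUANTILES}
        return cls(d0, d1, mu0, sigma0, contrast, q)

    @property
    def median(self) -> float:
        return self.quantiles[50]

    def to_dict(self) -> Dict[str, object]:
        return {
            "d0_samples": self.d0_samples.tolist(),
            "d1_samples": self.d1_samples.tolist(),
            "mu0": self.mu0,
            "sigma0": self.sigma0,
            "contrast_samples": self.contrast_samples.tolist(),
            "quantiles": {str(k): v for k, v in self.quantiles.items()},
        }


def _draw_population_graphs(
    null_spec: EnsembleSpec,
    alt_spec: EnsembleSpec,
    n_samples: int,
    seed: int,
) -> Tuple[List[Tuple[Graph, Graph]], List[Tuple[Graph, Graph]]]:
    """Independent (G0, G0') null pairs and (G0, G1) cross pairs."""
    ss = np.random.SeedSequence(entropy=seed)
    seeds = [int(s % (2**31)) for s in ss.generate_state(4 * n_samples, np.uint64)]
    null_pairs = []
    cross_pairs = []
    for i in range(n_samples):
        s0, s1, s2, s3 = seeds[4 * i : 4 * i + 4]
        null_pairs.append((sample(null_spec, s0), sample(null_spec, s1)))
        cross_pairs.append((sample(null_spec, s2), sample(alt_spec, s3)))
    return null_pairs, cross_pairs


def population_contrast(
    null_spec: EnsembleSpec,
    alt_spec: EnsembleSpec,
    distance: str | DistanceFn,
    n_samples: int = 20,
    seed: int = 0,
    distance_params: Mapping[str, object] | None = None,
) -> ContrastSummary:
    """Contrast of ``alt_spec`` against ``null_spec`` under one distance.

    Each of the ``n_samples`` D0 samples is the distance between two fresh
    independent null draws; each D1 sample is the distance between a fresh
    null draw and a fresh alternative draw.  All draws are seeded
    deterministically from ``seed``.
    """
    if n_samples < 3:
        raise GraphValidationError("n_samples must be at least 3")
    fn = (
        get_distance(distance, **(distance_params or {}))
        if isinstance(distance, str)
        else distance
    )
    null_pairs, cross_pairs = _draw_population_graphs(
        null_spec, alt_spec, n_samples, seed
    )
    d0 = [fn(a, b) for a, b in null_pairs]
    d1 = [fn(a, b) for a, b in cross_pairs]
    return ContrastSummary.from_samples(d0, d1)


def population_contrasts(
    null_spec: EnsembleSpec,
    alt_spec: EnsembleSpec,
    distances: Mapping[str, Tuple[str, Mapping[str, object]]],
    n_samples: int = 20,
    seed: int = 0,
) -> Dict[str, ContrastSummary]:
    """Contrasts for several distances on one shared set of graph draws.

    ``distances`` maps a label to ``(distance_name, params)``.  Sharing the
    draws makes the per-distance summaries directly comparable and avoids
    regenerating the ensembles; with the same seed, each summary is identical
    to the corresponding single-distance :func:`population_contrast`.
    """
    if n_samples < 3:
        raise GraphValidationError("n_samples must be at least 3")
    fns = {
        label: get_distance(name, **dict(params or {}))
        for label, (name, params) in distances.items()
    }
    null_pairs, cross_pairs = _draw_population_graphs(
        null_spec, alt_spec, n_samples, seed
    )
    out: Dict[str, ContrastSummary] = {}
    for label, fn in fns.items():
        d0 = [fn(a, b) for a, b in null_pairs]
        d1 = [fn(a, b) for a, b in cross_pairs]
        out[label] = ContrastSummary.from_samples(d0, d1)
    return out


def spectral_k_sweep(
    null_spec: EnsembleSpec,
    alt_spec: EnsembleSpec,
    kind: str,
    k_values: Sequence[int],
    p: float = 2.0,
    n_samples: int = 20,
    seed: int = 0,
) -> Dict[int, ContrastSummary]:
    """Contrast as a function of the spectral truncation ``k``.

    The same graph draws (hence the same full spectra) are shared across all
    ``k`` — a paired design that isolates the effect of the truncation.
    ``k = n`` reproduces the full-spectrum :func:`population_contrast`
    bit-for-bit under the same seed.
    """
    if n_samples < 3:
        raise GraphValidationError("n_samples must be at least 3")
    null_pairs, cross_pairs = _draw_population_graphs(
        null_spec, alt_spec, n_samples, seed
    )
    kmax = max(k_values)

    def spectrum_pair(pair):
        g, h = pair
        if kmax > min(g.n, h.n):
            raise GraphValidationError(
                f"max k {kmax} exceeds graph size {min(g.n, h.n)}"
            )
        return (
            spectra.compute_spectrum(g, kind).values,
            spectra.compute_spectrum(h, kind).values,
        )

    null_spectra = [spectrum_pair(pr) for pr in null_pairs]
    cross_spectra = [spectrum_pair(pr) for pr in cross_pairs]

    out: Dict[int, ContrastSummary] = {}
    for k in k_values:
        d0 = [spectra._lp(a[:k] - b[:k], p) for a, b in null_spectra]
        d1 = [spectra._lp(a[:k] - b[:k], p) for a, b in cross_spectra]
        out[int(k)] = ContrastSummary.from_samples(d0, d1)
    return out


@dataclass(frozen=True)
class TemporalSeries:
    """Distances between consecutive snapshots of a dynamic graph."""

    times: Tuple[int, ...]
    differences: np.ndarray
    normalized: np.ndarray | None

    def argmax_time(self) -> int:
        """Snapshot index at which the difference series peaks."""
        return int(self.times[int(np.argmax(self.differences))])


def temporal_differences(
    snapshots: Sequence[Graph],
    distance: str | DistanceFn,
    distance_params: Mapping[str, object] | None = None,
) -> TemporalSeries:
    """Difference series D(t_i) = d(G_{t_{i-1}}, G_{t_i}) and its
    mean-normalized version D(t)/mean(D)."""
    if len(snapshots) < 2:
        raise GraphValidationError("temporal_differences needs >= 2 snapshots")
    name = distance if isinstance(distance, str) else None
    fn = (
        get_distance(distance, **(distance_params or {}))
        if isinstance(distance, str)
        else distance
    )
    if name in CORRESPONDENCE_DISTANCES:
        sizes = {g.n for g in snapshots}
        if len(sizes) > 1:
            raise SizeMismatchError(
                f"{name} requires a fixed vertex set; snapshot sizes {sorted(sizes)}"
            )
    diffs = np.array(
        [fn(snapshots[t - 1], snapshots[t]) for t in range(1, len(snapshots))]
    )
    mean = diffs.mean()
    if mean > 0:
        normalized = diffs / mean
    else:
        import warnings

        warnings.warn("all temporal differences are zero; skipping normalization")
        normalized = None
    return TemporalSeries(tuple(range(1, len(snapshots))), diffs, normalized)


@dataclass(frozen=True)
class EdgewiseContrast:
    """Per-edge studentized contrast between two correlation-matrix populations."""

    values: np.ndarray
    undefined: np.ndarray  # boolean mask of zero-variance entries

    def top_pairs(self, count: int) -> List[Tuple[int, int]]:
        """The ``count`` vertex pairs with the largest contrast."""
        n = self.values.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        vals = self.values[iu, ju]
        order = np.argsort(vals)[::-1][:count]
        return [(int(iu[o]), int(ju[o])) for o in order]


def edgewise_contrast(
    pop0: Sequence[CorrelationMatrix], pop1: Sequence[CorrelationMatrix]
) -> EdgewiseContrast:
    """Entry (i, j) = (mean over pop1 - mean over pop0) / std over pop0.

    The null population pop0 must have at least two matrices so the sample
    standard deviation (Bessel-corrected) is defined; entries where it is
    zero are flagged undefined and set to NaN.  The diagonal is 0.
    """
    if len(pop0) < 2:
        raise GraphValidationError("pop0 needs >= 2 matrices for a nonzero std")
    if not pop1:
        raise GraphValidationError("pop1 must be non-empty")
    shapes = {m.values.shape for m in list(pop0) + list(pop1)}
    if len(shapes) > 1:
        raise SizeMismatchError(f"mixed matrix shapes {sorted(shapes)}")
    a0 = np.stack([m.values for m in pop0])
    a1 = np.stack([m.values for m in pop1])
    mean0 = a0.mean(axis=0)
    std0 = a0.std(axis=0, ddof=1)
    mean1 = a1.mean(axis=0)
    undefined = std0 == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(undefined, np.nan, (mean1 - mean0) / np.where(undefined, 1, std0))
    np.fill_diagonal(vals, 0.0)
    np.fill_diagonal(undefined, False)
    return EdgewiseContrast(vals, undefined)
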