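"""Random-graph ensembles, volume matching, and synthetic study populations.

Implements the generative procedures used throughout the benchmark:

* ``er`` — Erdős–Rényi G(n, p): each edge independent with probability p.
* ``sbm`` — two balanced communities (sizes differ by at most one vertex);
  within-community edge probability ``p_in``, cross-community ``q_out``.
* ``pa`` — preferential attachment: start from a star on ``l + 1`` vertices
  (vertex ``l`` is the hub of degree ``l``), then attach each new vertex to
  ``l`` distinct existing vertices with probability proportional to current
  degree.  The edge count is deterministic: ``|E| = l (n - l)``.
* ``ws`` — Watts–Strogatz: ring lattice with each vertex joined to its ``k``
  nearest neighbors (``k/2`` per side); each edge ``(i, j)``, taken in ring
  order, is rewired to ``(i, l)`` with probability ``beta``, with ``l``
  uniform among vertices that are not ``i`` and not already adjacent to
  ``i``; if no admissible target exists the edge is kept.  Edge count
  ``n k / 2`` is conserved.
* ``config`` — configuration model targeting simple graphs: stub pairing
  with full restart whenever a self-loop or parallel edge occurs
  (approximately uniform over simple graphs with the degree sequence).
* ``lattice`` — deterministic 2-d rectangular grid ``x`` by ``y``.

Sampling is deterministic given ``(spec, seed)``: the PCG64 generator is
seeded from ``SeedSequence(seed, spawn_key=(attempt,))`` so connectivity
rejection consumes independent substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .errors import GraphValidationError, SamplingError
from .graph_core import CorrelationMatrix, Graph, is_connected

MODELS = ("er", "sbm", "pa", "ws", "config", "lattice")

#: connectivity conditioning is on by default for models that can plausibly
#: produce disconnected draws at benchmark densities; pa is connected by
#: construction and the lattice is deterministic
_DEFAULT_CONNECTED = {"er": True, "sbm": True, "ws": True,
                      "pa": False, "config": False, "lattice": False}


@dataclass(frozen=True)
class EnsembleSpec:
    """A random-graph model tag, its parameters, and sampling constraints."""

    model: str
    params: Mapping[str, object] = field(default_factory=dict)
    require_connected: bool | None = None
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise GraphValidationError(
                f"unknown model {self.model!r}; expected one of {MODELS}"
            )
        object.__setattr__(self, "params", dict(self.params))
        if self.require_connected is None:
            object.__setattr__(
                self, "require_connected", _DEFAULT_CONNECTED[self.model]
            )
        if self.max_retries < 1:
            raise GraphValidationError("max_retries must be positive")

    def to_dict(self) -> Dict[str, object]:
        params = dict(self.params)
        if isinstance(params.get("match"), EnsembleSpec):
            params["match"] = params["match"].to_dict()
        return {
            "model": self.model,
            "params": params,
            "require_connected": self.require_connected,
            "max_retries": self.max_retries,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "EnsembleSpec":
        params = dict(d.get("params", {}))
        if isinstance(params.get("match"), Mapping):
            params["match"] = cls.from_dict(params["match"])
        return cls(
            model=d["model"],
            params=params,
            require_connected=d.get("require_connected"),
            max_retries=int(d.get("max_retries", 1000)),
        )


def _rng(seed: int, attempt: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(attempt,)))
    )


def _sbm_sizes(n: int) -> Tuple[int, int]:
    return (n - n // 2, n // 2)


def _draw_er(rng: np.random.Generator, n: int, p: float) -> Graph:
    if not 0.0 <= p <= 1.0:
        raise GraphValidationError(f"p must be in [0, 1], got {p}")
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    return Graph.from_edges(n, zip(iu[mask].tolist(), ju[mask].tolist()))


def _draw_sbm(rng: np.random.Generator, n: int, p_in: float, q_out: float) -> Graph:
    n1, _ = _sbm_sizes(n)
    iu, ju = np.triu_indices(n, k=1)
    same = (iu < n1) == (ju < n1)
    probs = np.where(same, p_in, q_out)
    mask = rng.random(len(iu)) < probs
    return Graph.from_edges(n, zip(iu[mask].tolist(), ju[mask].tolist()))


def _draw_pa(rng: np.random.Generator, n: int, l: int) -> Graph:
    if not 1 <= l < n:
        raise GraphValidationError(f"pa requires 1 <= l < n, got l={l}, n={n}")
    deg = np.zeros(n)
    edges: List[Tuple[int, int]] = []
    # star on vertices 0..l with hub l
    for v in range(l):
        edges.append((v, l))
    deg[:l] = 1.0
    deg[l] = float(l)
    for i in range(l + 1, n):
        targets: List[int] = []
        avail = deg[:i].copy()
        for _ in range(l):
            probs = avail / avail.sum()
            t = int(rng.choice(i, p=probs))
            targets.append(t)
            avail[t] = 0.0  # without replacement: simple graph
        for t in targets:
            edges.append((t, i))
            deg[t] += 1.0
        deg[i] = float(l)
    return Graph.from_edges(n, edges)


def _draw_ws(rng: np.random.Generator, n: int, k: int, beta: float) -> Graph:
    if k % 2 != 0 or not 0 < k < n:
        raise GraphValidationError(f"ws requires even 0 < k < n, got k={k}")
    if not 0.0 <= beta <= 1.0:
        raise GraphValidationError(f"beta must be in [0, 1], got {beta}")
    adj = [set() for _ in range(n)]

    def add(u: int, v: int) -> None:
        adj[u].add(v)
        adj[v].add(u)

    def remove(u: int, v: int) -> None:
        adj[u].discard(v)
        adj[v].discard(u)

    for lane in range(1, k // 2 + 1):
        for i in range(n):
            add(i, (i + lane) % n)
    # rewire in ring order (lane-major), matching the construction order
    for lane in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + lane) % n
            if j not in adj[i]:
                continue  # already rewired away
            if rng.random() >= beta:
                continue
            candidates = [v for v in range(n) if v != i and v not in adj[i]]
            if not candidates:
                continue  # no admissible target: keep the edge
            l_target = candidates[int(rng.integers(len(candidates)))]
            remove(i, j)
            add(i, l_target)
    edges = [(i, j) for i in range(n) for j in adj[i] if i < j]
    return Graph.from_edges(n, edges)


def check_degree_sequence(degs: Sequence[int]) -> None:
    """Reject degree sequences with odd sum or violating Erdős–Gallai."""
    degs = sorted((int(d) for d in degs), reverse=True)
    if any(d < 0 for d in degs):
        raise GraphValidationError("degrees must be non-negative")
    if sum(degs) % 2 != 0:
        raise GraphValidationError("degree sequence has odd sum")
    n = len(degs)
    prefix = np.cumsum(degs)
    for r in range(1, n + 1):
        rhs = r * (r - 1) + sum(min(d, r) for d in degs[r:])
        if prefix[r - 1] > rhs:
            raise GraphValidationError(
                f"degree sequence violates the Erdős–Gallai condition at k={r}"
            )


def _draw_config(
    rng: np.random.Generator, degs: Sequence[int], max_restarts: int = 100
) -> Graph:
    degs = [int(d) for d in degs]
    check_degree_sequence(degs)
    n = len(degs)
    stubs = np.repeat(np.arange(n), degs)
    if len(stubs) == 0:
        return Graph(n, {})
    for _ in range(max_restarts):
        perm = rng.permutation(stubs)
        pairs = perm.reshape(-1, 2)
        seen = set()
        ok = True
        for u, v in pairs:
            u, v = int(u), int(v)
            if u == v:
                ok = False
                break
            e = (u, v) if u < v else (v, u)
            if e in seen:
                ok = False
                break
            seen.add(e)
        if ok:
            return Graph.from_edges(n, seen)
    # Heavy-tailed sequences make rejection hopeless: the probability of a
    # simple stub pairing decays like exp(-d_max^2 / 4m).  Fall back to a
    # Havel-Hakimi realization randomized by double edge swaps, the standard
    # MCMC route to an approximately uniform simple graph with exact degrees.
    import networkx as nx

    g = nx.havel_hakimi_graph(degs)
    m = g.number_of_edges()
    if m > 1:
        nx.double_edge_swap(
            g,
            nswap=10 * m,
            max_tries=500 * m,
            seed=int(rng.integers(2**31)),
        )
    return Graph.from_edges(n, g.edges())


def _draw_lattice(x: int, y: int) -> Graph:
    if x < 1 or y < 1:
        raise GraphValidationError("lattice dimensions must be positive")
    edges = []
    for r in range(x):
        for c in range(y):
            v = r * y + c
            if c + 1 < y:
                edges.append((v, v + 1))
            if r + 1 < x:
                edges.append((v, v + y))
    return Graph.from_edges(x * y, edges)


def _draw_once(spec: EnsembleSpec, rng: np.random.Generator, seed: int) -> Graph:
    p = spec.params
    if spec.model == "er":
        return _draw_er(rng, int(p["n"]), float(p["p"]))
    if spec.model == "sbm":
        return _draw_sbm(rng, int(p["n"]), float(p["p_in"]), float(p["q_out"]))
    if spec.model == "pa":
        return _draw_pa(rng, int(p["n"]), int(p["l"]))
    if spec.model == "ws":
        return _draw_ws(rng, int(p["n"]), int(p["k"]), float(p["beta"]))
    if spec.model == "config":
        if "match" in p:
            ref = sample(p["match"], seed=int(rng.integers(2**31)))
            from .graph_core import degrees as _degrees

            degs = np.rint(_degrees(ref)).astype(int)
        else:
            degs = p["degrees"]
        return _draw_config(rng, degs)
    if spec.model == "lattice":
        return _draw_lattice(int(p["x"]), int(p["y"]))
    raise GraphValidationError(f"unknown model {spec.model!r}")


def sample(spec: EnsembleSpec, seed: int) -> Graph:
    """Draw one graph from the ensemble, deterministically in ``(spec, seed)``.

    With ``require_connected`` the draw is rejection-resampled until
    connected; exhausting ``max_retries`` raises :class:`SamplingError`
    reporting the empirical rejection rate.
    """
    for attempt in range(spec.max_retries):
        g = _draw_once(spec, _rng(seed, attempt), seed)
        if not spec.require_connected or is_connected(g):
            return g
    raise SamplingError(
        f"{spec.model} sampler exhausted {spec.max_retries} retries waiting "
        f"for a connected draw (empirical rejection rate 1.0 over "
        f"{spec.max_retries} attempts); lower the connectivity requirement "
        "or increase density"
    )


# -- volume matching -----------------------------------------------------------


def expected_volume(spec: EnsembleSpec) -> float:
    """Expected number of edges of the ensemble (exact count where deterministic)."""
    p = spec.params
    if spec.model == "er":
        n = int(p["n"])
        return float(p["p"]) * math.comb(n, 2)
    if spec.model == "sbm":
        n = int(p["n"])
        n1, n2 = _sbm_sizes(n)
        return float(p["p_in"]) * (math.comb(n1, 2) + math.comb(n2, 2)) + float(
            p["q_out"]
        ) * n1 * n2
    if spec.model == "pa":
        n, l = int(p["n"]), int(p["l"])
        return float(l * (n - l))
    if spec.model == "ws":
        return int(p["n"]) * int(p["k"]) / 2.0
    if spec.model == "lattice":
        x, y = int(p["x"]), int(p["y"])
        return float(x * (y - 1) + y * (x - 1))
    if spec.model == "config":
        if "match" in p:
            return expected_volume(p["match"])
        return float(sum(int(d) for d in p["degrees"]) / 2.0)
    raise GraphValidationError(f"unknown model {spec.model!r}")


def match_volume_er(spec: EnsembleSpec) -> float:
    """Erdős–Rényi edge probability with the same expected volume as ``spec``.

    For preferential attachment this is the printed ``p(l) = l(n-l)/C(n,2)``.
    """
    if spec.model not in ("pa", "ws", "sbm"):
        raise GraphValidationError(
            f"volume matching is defined for pa, ws, sbm; got {spec.model!r}"
        )
    n = int(spec.params["n"])
    return expected_volume(spec) / math.comb(n, 2)


def matched_er_spec(spec: EnsembleSpec, require_connected: bool = True) -> EnsembleSpec:
    """The volume-matched Erdős–Rényi null for ``spec``."""
    n = int(spec.params["n"])
    return EnsembleSpec(
        "er", {"n": n, "p": match_volume_er(spec)}, require_connected=require_connected
    )


def matched_config_spec(spec: EnsembleSpec) -> EnsembleSpec:
    """Degree-matched configuration null: each draw samples ``spec`` and
    randomizes it to a uniform simple graph with the same degree sequence."""
    return EnsembleSpec("config", {"match": spec})


# -- synthetic study populations ----------------------------------------------


def dynamic_sbm_stream(
    n: int = 100,
    p_in: float = 0.3,
    q_out: float = 0.01,
    n_steps: int = 8,
    change_step: int = 4,
    step_factor: float = 5.0,
    seed: int = 0,
) -> List[Graph]:
    """A dynamic two-community SBM with one planted change point.

    Every snapshot independently resamples all edges (full within-community
    churn); from snapshot ``change_step`` onward the cross-community density
    is multiplied by ``step_factor``.  The temporal difference between
    snapshots ``change_step - 1`` and ``change_step`` is the planted event: a
    global connectivity change hidden under heavy local churn.
    """
    if not 1 <= change_step < n_steps:
        raise GraphValidationError("change_step must lie strictly inside the stream")
    snaps = []
    for t in range(n_steps):
        q = q_out * (step_factor if t >= change_step else 1.0)
        spec = EnsembleSpec("sbm", {"n": n, "p_in": p_in, "q_out": q})
        snaps.append(sample(spec, seed=int(np.random.SeedSequence(
            entropy=seed, spawn_key=(10_000 + t,)).generate_state(1)[0] % (2**31))))
    return snaps


def synthetic_correlation_population(
    n_subjects: int,
    n_regions: int = 116,
    elevated_pairs: Sequence[Tuple[int, int]] = (),
    elevation: float = 0.3,
    noise_std: float = 0.1,
    seed: int = 0,
) -> List[CorrelationMatrix]:
    """Synthetic population of region-by-region correlation matrices.

    Stands in for connectome populations: each subject's matrix is a zero
    baseline plus ``elevation`` on the planted pairs plus i.i.d. symmetric
    Gaussian noise of standard deviation ``noise_std``, clipped to
    ``[-0.999, 0.999]``, with unit diagonal.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    base = np.zeros((n_regions, n_regions))
    for (i, j) in elevated_pairs:
        base[i, j] = base[j, i] = elevation
    out = []
    for _ in range(n_subjects):
        noise = rng.normal(scale=noise_std, size=(n_regions, n_regions))
        noise = (noise + noise.T) / np.sqrt(2.0)  # keep marginal std = noise_std
        m = np.clip(base + noise, -0.999, 0.999)
        np.fill_diagonal(m, 1.0)
        out.append(CorrelationMatrix(m))
    return out
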