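# Methods

This note documents the models and procedures implemented in `netdist`, the
conventions and defaults chosen where several were defensible, and what the
synthetic benchmarks do and do not demonstrate.

## Graphs and matrix representations

Graphs are simple, undirected, with strictly positive weights and 0-based
vertex indices (1-based labels in input files are not supported; the I/O
layer reports offending lines). The three matrix representations are the
adjacency matrix `A`, the combinatorial Laplacian `L = D − A` with `D` the
diagonal weighted-degree matrix, and the normalized Laplacian
`𝓛 = D^{-1/2} L D^{-1/2}` with the convention `D^{-1/2}_{ii} = 0` for
isolated vertices, so an isolated vertex contributes an all-zero row and
column. Eigenvalues of `𝓛` lie in `[0, 2]`; the multiplicity of the zero
eigenvalue of `L` equals the number of connected components (both facts are
exercised as invariants in the test suite).

Connectome construction takes a correlation matrix with unit diagonal and
thresholds absolute correlations: edge `(u, v)` present iff `|ρ(u,v)| ≥ T`,
weighted by `|ρ(u,v)|` or binarized. The diagonal is excluded (no
self-loops) and isolated regions are retained so the vertex set always
matches the atlas dimension.

## Spectral distances

`compute_spectrum` orders adjacency eigenvalues descending and Laplacian
eigenvalues ascending, so a truncation to `k` eigenvalues always keeps the
structurally informative extreme: the large adjacency eigenvalues carry
coarse structure (community splits appear in `λ₂^A`), the small Laplacian
eigenvalues carry connectivity and cluster structure, and the upper tail of
the combinatorial-Laplacian spectrum tracks the degree distribution.
Distances are `ℓ_p` norms of the difference of (truncated) spectra,
`p = 2` by default; `p = 0` counts entries differing beyond `1e-8`,
`p = ∞` is the maximum difference, and `p < 1` is allowed with a warning
that it is not a true metric. Spectral distances are pseudometrics:
cospectral non-isomorphic graphs are at distance zero, which is accepted
rather than worked around.

Graphs of different sizes can only be compared with an explicit
`k ≤ min(n, n′)`. No zero-padding convention is imposed, because padding
silently mixes "missing vertex" with "zero eigenvalue".

Dense symmetric eigendecomposition is used up to `n = 2000`; beyond that an
iterative sparse solver (tolerance `1e-8`, fixed deterministic starting
vector) with explicit `k` takes over.

## Matrix distances

All matrix distances require node correspondence and reject size
mismatches. Norms are entrywise `ℓ₁` over the full matrix, so each
undirected pair is counted twice; the contrast statistic is invariant to
such global factors.

**Effective resistance** is computed from the Moore–Penrose pseudoinverse of
the combinatorial Laplacian, obtained by eigendecomposition with eigenvalues
below `1e-10 × λ_max` dropped. On a connected graph `R` is a metric on the
vertices; on trees it coincides with shortest-path length; it is undefined
across components. The **renormalized resistance** `ρ = R/(1+R)` (with
`ρ = 1` across components, the `R → ∞` limit) is the bounded extension used
whenever disconnected graphs must be compared; within a component it is a
strictly monotone transform of `R`, preserving all affinity rankings.

**Single-edge closed form.** For a perturbation `Δw` of edge `(i₀, j₀)` of
a connected graph, the resistance-perturbation distance has the exact form

    d = 2n · |Δw| / (1 + Δw·R_{i₀j₀}) · Σ_{k≥2} (φ_k(i₀) − φ_k(j₀))² / λ_k²

with `λ_k, φ_k` the eigenpairs of the **combinatorial** Laplacian in
ascending order. The derivation is a Sherman–Morrison rank-one update of
`L†`: with `x = L†(e_{i₀} − e_{j₀})`, every entry of `R` changes by
`−c(x_u − x_v)²` for the same scalar `c`, and `Σ_{u,v}(x_u − x_v)² = 2n‖x‖²`
because `x ⊥ 1`. The combinatorial-Laplacian convention is the one that
agrees with direct recomputation of both resistance matrices (relative error
below `1e-6` over random graphs in the test suite); a normalized-Laplacian
reading of the same formula does not. When `1 + Δw·R_{i₀j₀}` reaches zero
the perturbation removes a bridge and the distance is genuinely undefined;
the implementation warns and lets the direct route raise the
disconnected-graph error.

**DeltaCon** compares `S = [I + ε²D − εA]^{-1}`, which weights neighbors at
path distance `k` by `ε^k` (`S = I + εA + ε²(A² − D) + O(ε³)`, verified
numerically at third order). Default `ε = 1/(1 + d_max)` over both graphs.
The comparison is the Matusita difference
`sqrt(Σ_ij (√S_ij − √S'_ij)²)` with negative entries clamped at zero before
the root; a `variant="frobenius"` form comparing raw entries without
radicals is also exposed, with Matusita the default.

## NetSimile

Seven per-node features: degree; clustering coefficient; mean neighbor
degree; mean neighbor clustering; egonet edge count; edges leaving the
egonet; distinct external neighbors of the egonet. Weighted graphs are
binarized for this distance. Each feature row is summarized by mean,
median, sample standard deviation, skewness and excess kurtosis (the latter
two mapped to 0 for constant rows, as on vertex-transitive graphs), giving
a 35-entry signature compared with the Canberra distance (0/0 terms
contribute 0). Aggregation sorts each feature row first, which makes the
signature exactly — bitwise — permutation invariant despite floating-point
non-associativity.

## Random-graph ensembles

All samplers are deterministic functions of `(spec, seed)` built on PCG64
with per-attempt substreams spawned by counter, so connectivity rejection
never perturbs other draws.

* **Erdős–Rényi** `G(n, p)`: independent edges.
* **Stochastic blockmodel**: two balanced communities (sizes differing by
  at most one vertex), within-density `p_in`, cross-density `q_out`. With
  `p_in = q_out` it reduces exactly to `G(n, p)` (checked distributionally).
* **Preferential attachment**: starts from a star on `l + 1` vertices (hub
  degree `l`), then each new vertex attaches to `l` distinct existing
  vertices, sequentially, with probability proportional to current degree
  (without replacement, so the graph stays simple). Edge count is exactly
  `l(n − l)`.
* **Watts–Strogatz**: ring lattice (`k/2` neighbors per side) rewired in
  ring construction order; each edge `(i, j)` is replaced by `(i, l)` with
  probability `β`, `l` uniform over non-adjacent targets; if no admissible
  target exists the edge is kept, so the edge count `nk/2` is conserved for
  every seed and `β`.
* **Configuration model**: stub pairing with full restart on self-loops or
  parallel edges. For heavy-tailed degree sequences the probability that a
  pairing is simple decays like `exp(−d_max²/4m)` and rejection is
  hopeless, so after 100 failed pairings the sampler switches to a
  Havel–Hakimi realization randomized by `10m` double edge swaps — the
  standard MCMC randomization of a simple graph with fixed degrees. The
  output degree sequence is always exact and the graph simple; uniformity
  over simple graphs is approximate (this was validated spectrally against
  an independent uniform sampler). A `match` parameter lets a spec draw a
  fresh reference graph (e.g. preferential attachment) per sample and
  randomize its degree sequence — the degree-matched null used in the
  benchmark experiments.
* **Lattice**: deterministic `x × y` rectangular grid with
  `x(y−1) + y(x−1)` edges.

Connectivity conditioning (rejection resampling) is on by default for
er/sbm/ws, off for pa (connected by construction), lattice (deterministic)
and config (the renormalized resistance handles disconnection).

**Volume matching.** `match_volume_er` returns the ER probability with the
same expected edge count as a given model: `p(l) = l(n−l)/C(n,2)` for
preferential attachment, `nk/2 / C(n,2)` for Watts–Strogatz, the
density-weighted block average for the blockmodel. Matching neutralizes
first-order (volume) differences so experiments probe structure, not size.
For the two-community blockmodel benchmark the ER null uses the
volume-matched probability; a fixed higher null density (chosen to force
connectivity) appears in one published description of this comparison but
is inconsistent with volume matching, and the matched value is used here.

## The contrast protocol

`D₀` samples are distances between two *fresh independent* null draws and
`D₁` between a fresh null and a fresh alternative draw, keeping samples
i.i.d.; the sample standard deviation uses the `n−1` denominator. Box
summaries report the 5/25/50/75/95 percentiles. The contrast is exactly
invariant under any rescaling `d → c·d`, so entrywise-norm double counting
and similar global factors never matter. Spectral `k`-sweeps reuse one set
of draws (and one full eigendecomposition per graph) across all truncations
— a paired design; at `k = n` the sweep reproduces the unswept computation
bit-for-bit under the same seed.

Reduced-scale defaults for the preset experiments: `n = 300` and 20
samples per distribution, with blockmodel densities `p_in = 1.9 × 0.04`,
`q_out = 0.1 × 0.04` (ratio 19), preferential attachment `l = 6`,
Watts–Strogatz `k = 20, β = 0.1`, lattice `30 × 10`. These keep every
preset within desk-scale runtime while preserving the expected-degree
regime of the full-scale study (`n = 1000`, 50 samples); full scale is a
matter of changing the spec parameters.

**Operational thresholds.** A median contrast above 2 is read as "the
distance separates the populations", a median magnitude below 1 as "fails
to separate". These are conventions for the automated checks, not
statistical significance levels.

## Synthetic study populations

**Dynamic blockmodel stream** (change-point benchmark): two communities of
50 (`n = 100`), within-density 0.3, cross-density 0.01; *every* snapshot
independently resamples all edges (full local churn), and from snapshot 4
of 8 the cross-density is multiplied by 5. The planted event is thus a
change in *global* connectivity hidden under maximal local turnover: the
resistance temporal series recovers it (≥ 90% of runs) because
inter-community resistance is governed by the number of cross edges, while
the edit distance — which counts churned edges — misses it in every run.
This emulates the community structure of real contact networks, not their
degree heterogeneity, burstiness, or partial overlap between snapshots.

**Correlation-matrix populations** (edgewise-contrast benchmark):
116-region matrices (a standard atlas dimension), zero baseline
correlation, i.i.d. symmetric Gaussian noise of std 0.1 per entry, and a
planted block of 10 pairs elevated by +0.3 in the alternative population;
20 subjects per population. The planted pairs are recovered as the top-10
contrasts in ≥ 95% of runs. Real connectome populations have correlated
noise, nonzero baseline structure, and much larger cohorts; passing this
benchmark shows the estimator ranks localized mean shifts correctly against
entrywise noise, not that it would survive confound structure in real data.

## Numerical choices

* Symmetry tolerance for matrix inputs: `1e-10`; eigensolver target `1e-8`.
* Laplacian pseudoinverse: eigendecomposition, dropping
  `λ < 1e-10 × λ_max`.
* Exact `O(n²)`-and-worse algorithms throughout (a warning fires above
  `n = 5000`); the fast approximate algorithms for DeltaCon and resistance
  are deliberately out of scope.
* Eigenvalue ties are resolved by value ordering only; distances never need
  eigenvector pairing.
* Degenerate inputs are errors, not NaNs: zero null variance rejects the
  contrast, a deterministic ensemble as null is rejected with an
  explanation, undefined edgewise entries (zero null std) are flagged and
  reported.

## Known limitations

* The configuration sampler is approximately, not exactly, uniform over
  simple graphs with the given degrees (Havel–Hakimi + swap randomization
  after stub-pairing gives up); its interface accepts a drop-in replacement.
* At the scales tested (n = 300 and n = 1000), the full-spectrum
  normalized-Laplacian distance *does* detect residual structure in
  preferential-attachment graphs beyond their degree sequence (median
  contrast ≈ 3.6 at n = 300 against the degree-matched configuration
  null, driven by the smallest nontrivial eigenvalues; truncated variants
  with small `k` do not). The corresponding acceptance check, which expects
  every distance to fail on this comparison, is intentionally left failing
  rather than weakened; the other six distances behave as expected.
* Directed graphs, multigraphs, ERGMs, graph kernels/GNN embeddings, and
  distances between graphs of different sizes without explicit truncation
  are out of scope.
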