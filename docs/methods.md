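# Methods

## The two network models

A protein-interaction network is represented at two levels.

The **1D graph model** `G = (V, E)` holds proteins and pairwise
interactions. Input edge lists may carry STRING-style integer
confidence scores (0–1000); edges below a user-chosen cutoff are
dropped at load time. Reciprocal directed pairs (i→j and j→i) collapse
to a single skeleton edge: topology and curvature are computed per
undirected edge, and direction is retained only to classify triangle
orientation.

The **2D simplicial-complex model** `C = (V, E, F)` promotes triangles
to faces. In a directed network an unordered triple is a face when all
three pairs are linked and the available arc directions admit a
feedforward loop (one vertex with two out-edges, one with two
in-edges) or a feedback loop (a directed 3-cycle). Since every
orientation of a triangle is either cyclic or transitive, any triple
whose three pairs are linked qualifies; the label is *feedback* when
any assignment of the available directions closes a 3-cycle (feedback
takes precedence over feedforward for triples with reciprocal arcs),
*feedforward* otherwise, and *undirected* for undirected input.
Ignoring `F` recovers the 1D model exactly; the Euler characteristic
χ = |V| − |E| + |F| separates the two models topologically.

Face enumeration intersects neighbour sets along a degree ordering
(each triangle visited once); for counting only, a sparse-matrix route
`sum(A²∘A)/6` handles proteome-scale networks in seconds.

## Expression-driven weights

Gene expression `x` (one sample) proxies protein abundance. The
mass-action law makes the propensity of interaction (i, j)
proportional to `x_i·x_j`; row-normalising over the neighbours of i
cancels the `x_i` factor and leaves the transition probability

    p_ij = x_j / Σ_{k∈N(i)} x_k .

This chain satisfies detailed balance on an undirected skeleton, giving
the closed-form stationary distribution `π_i ∝ x_i Σ_{k∈N(i)} x_k`.
The entropy rate `SR = Σ_i π_i S_i` with `S_i = −Σ_j p_ij log p_ij`
(natural log, unnormalised by default; normalisation by log max-degree
is an option) summarises walk heterogeneity: `0 ≤ SR ≤ log(max
degree)`, with equality approached for uniform expression.

Geometric weights follow a resistance quasimetric:

- `w(e_ij) = 1 / p̄_ij`, where `p̄` is by default the arithmetic mean
  of the two directed probabilities (options `min`, `max`). The mean
  keeps `w` finite whenever either direction is positive and treats
  the two directions symmetrically.
- `w(v) = π_v` by default, so the curvature weights and the global
  averaging measure coincide; `w(v) = x_v` is available and is a
  results-sensitive choice.
- `w(f) = (w(e1)w(e2)w(e3))^(2/3)` by default — the squared geometric
  mean of the boundary edges, which has the dimension of an edge
  weight squared and therefore behaves like an area. Options:
  `product`, `mean`, `max`.

Normalisation: `cpm_log1p` (counts-per-million then log1p) by default,
or `none`; a pseudocount (default 1e-3) is added after normalisation
so every weight is strictly positive and the chain is well defined.
Genes present in the network but absent from the matrix are dropped by
restricting the network to the measured genes and then to its largest
connected component (the stationary distribution requires a connected
chain).

## Curvature

Forman's combinatorial Ricci curvature is evaluated exactly as written
in its weighted-complex form (README shows the formula), together with
the face-free graph restriction. Two structural facts are exploited:

- two distinct boundary edges of a triangle always share a vertex, so
  "shares a face but not a vertex" cannot occur on a simplicial
  2-complex and parallel edges are exactly the vertex-sharing edges
  with no common face;
- two distinct edges share at most one vertex, so the inner vertex sum
  has at most one term.

The `CurvatureEngine` precomputes the incidence and parallel-edge
lists once per complex and reuses them across samples, which is what
makes per-cell scans over many samples cheap. A single-edge functional
form (`forman_ricci_2d` / `forman_ricci_1d`) applies the definition
directly from sets and serves readability; both routes are checked
against each other and against an independent naive evaluator in the
tests (agreement to 1e-10 on random weighted complexes).

Contraction uses the unweighted incident-edge count:
`F(v) = (1/deg v) Σ_{e∼v} F(e)`, and `F_GA = Σ_i π_i F(v_i)`.

## Statistics

Per-gene differential testing between two sample groups uses the
two-sided Wilcoxon rank-sum (Mann-Whitney) test — exact at small
sample sizes without ties, normal approximation otherwise — with
Benjamini-Hochberg correction; genes constant in both groups get
p = 1. The choice of this test mirrors the group-level testing used
elsewhere in the pipeline and is an assumption, not a theorem.
Direction is the sign of the mean difference, and enrichment runs
separately on up- and down-shifted hit lists. Overrepresentation is
the one-sided hypergeometric tail over GMT sets intersected with the
background (default: all network genes present in the matrix), BH
across sets, annotated with the mean curvature shift of the
overlapping genes. Classifier evaluation uses the rank-based AUC (ties
half) and DeLong's covariance-based test for differences of paired
AUCs; a zero-variance difference with identical AUCs yields p = 1 by
contract.

## Synthetic data

The generators exist so that every stage is testable without
downloads; they do not emulate any particular experiment.

- `synthetic_network` starts from a uniform G(n, m) graph and performs
  triadic-closure rewiring: open wedges are closed by relocating a
  uniformly chosen existing edge, preserving the edge count exactly.
  `triangle_enrichment` scales the number of rewiring attempts, so 0
  is exactly Erdős-Rényi and the expected triangle count rises
  monotonically. A base of G(n, m) (rather than preferential
  attachment) was chosen so the enrichment-0 triangle count has the
  closed-form ER expectation `C(n,3)(m/C(n,2))³` to test against; real
  PPI degree distributions are heavier-tailed than this.
- `synthetic_expression` draws negative-binomial counts
  (Var = μ + αμ², default α = 0.3, log-normal gene means) and
  multiplies planted genes' means by `effect_size` in group B *before*
  normalisation, so the pipeline's normalisation choices are
  exercised. Defaults (200 genes, 50 samples per group, 20 planted,
  effect 4) give the differential-expression pipeline near-complete
  recovery; the null (effect 1) yields uniform p-values.

What passing these tests shows: correctness of the machinery and
sensible operating characteristics under clean count noise. What they
do not show: behaviour under dropout, batch effects, library-size
extremes, or the degree structure of real interactomes.

## Numerical choices

- Stationary distributions use the detailed-balance closed form when
  the defining expression vector is available; otherwise power
  iteration on the lazy chain (P+I)/2 (same fixed point, aperiodic
  even on bipartite skeletons) to a 1e-12 residual.
- All dictionaries are accumulated in deterministic sorted order;
  repeated runs are byte-identical for fixed seeds.
- Power-law fits use unit-width integer bins, drop zero-probability
  bins, natural logs; a flat distribution (zero variance in log P)
  reports r² = 0 by contract.
- Test comparisons use 1e-9 absolute tolerance for curvature values
  and 1e-10 for the oracle-equivalence checks.

## Problem sizes

The test suite and `scripts/acceptance.py` run the random-network
topology comparison at the full interactome scale (11,888 vertices,
315,130 edges; sparse triangle counting makes this a few seconds per
seed). Curvature oracle checks use 50 random complexes of up to 25
vertices; the end-to-end curvature recovery experiment uses a
60-vertex network with 30 cells per group over 50 replicates; the null
false-discovery-rate check uses 200 replicates of a 200-gene,
20-vs-20 design.

## Known limitations

- Curvature of cells above dimension 2, Ollivier-Ricci curvature and
  Ricci flow are out of scope.
- The weighting scheme (symmetrisation, vertex-weight source, face
  rule) has defensible alternatives; defaults are stated above and
  exposed in `WeightingConfig`, and global curvature values do depend
  on them.
- Vertex weights default to π, coupling the curvature weights to the
  averaging measure; with `expression` weights the two decouple.
- The per-sample loop is serial; per-cell curvature over very large
  complexes (millions of faces) is not optimised beyond the shared
  incidence precomputation.
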