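"""Synthetic networks, expression matrices and toy complexes.

Real inputs to the pipeline are proteome-scale interaction databases
and single-cell expression matrices; the generators here produce
structurally similar stand-ins with known ground truth so every stage
is testable offline.  Networks come from a uniform G(n, m) base with a
triadic-closure rewiring step that enriches triangles above the random
expectation while preserving edge count; expression matrices are
negative-binomial counts with a multiplicative shift planted in a known
gene subset of one group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complex_builder import InteractionNetwork, erdos_renyi_network
from .weighting import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "toy_complexes",
    "synthetic_network",
    "synthetic_expression",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a two-group synthetic expression experiment.

    ``dispersion`` is the negative-binomial overdispersion α in
    Var = μ + α·μ² (α = 0.3 is typical of UMI single-cell counts);
    ``effect_size`` multiplies the mean of the planted genes in group B.
    """

    n_genes: int = 200
    n_samples: int = 50  # per group
    n_planted: int = 20
    effect_size: float = 4.0
    dispersion: float = 0.3
    mean_log_mu: float = math.log(50.0)
    sd_log_mu: float = 1.0
    seed: int = 0
    planted_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


def toy_complexes() -> dict[str, InteractionNetwork]:
    """Named small fixtures with known unit-weight curvature.

    isolated_edge
        single edge; unit-weight 1D curvature 2 (= 4 − 1 − 1).
    path3
        a–b–c; 1D curvatures (1, 1).
    cycle5
        C₅; every edge has 1D curvature 0 (= 4 − 2 − 2), no faces.
    star5
        hub with 5 leaves; edge curvature 4 − 6 − 1 = −3.
    filled_triangle
        undirected K₃, one face; 2D curvature 3 on every edge.
    ffl / fbl
        directed triangles in feedforward / feedback orientation.
    two_faces
        complex {abc, abd}: shared edge ab has unit-weight 2D
        curvature 4.
    face_free
        a 4-cycle: triangle-free, so the 2D model reduces to 1D.
    """
    def undirected(edges):
        return InteractionNetwork.from_edges(edges, directed=False)

    def directed(edges):
        return InteractionNetwork.from_edges(edges, directed=True)

    return {
        "isolated_edge": undirected([("a", "b")]),
        "path3": undirected([("a", "b"), ("b", "c")]),
        "cycle5": undirected([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "e")]),
        "star5": undirected([("hub", f"leaf{i}") for i in range(1, 6)]),
        "filled_triangle": undirected([("a", "b"), ("a", "c"), ("b", "c")]),
        "ffl": directed([("a", "b"), ("b", "c"), ("a", "c")]),
        "fbl": directed([("a", "b"), ("b", "c"), ("c", "a")]),
        "two_faces": undirected(
            [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d")]
        ),
        "face_free": undirected([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]),
    }


def synthetic_network(
    n_vertices: int,
    target_mean_degree: float,
    triangle_enrichment: float = 0.0,
    directed_fraction: float = 0.0,
    seed: int = 0,
) -> InteractionNetwork:
    """Random network with tunable triangle excess over G(n, m).

    Starts from a uniform G(n, m) graph with m = n·d/2 edges, then
    performs triadic-closure rewiring: open wedges i–j–k are closed by
    moving a uniformly chosen existing edge onto the pair (i, k).  The
    number of rewiring attempts is ``triangle_enrichment · m``, so the
    edge count is preserved exactly, enrichment 0 is exactly Erdős-Rényi
    and the expected triangle count grows monotonically with the
    enrichment parameter.  ``directed_fraction`` of the final edges are
    given a random single direction (the rest become reciprocal arcs)
    when positive.
    """
    if n_vertices < 3 or target_mean_degree <= 0:
        raise ValueError("need >= 3 vertices and positive mean degree")
    if triangle_enrichment < 0 or not 0 <= directed_fraction <= 1:
        raise ValueError("infeasible enrichment or directed fraction")
    m = round(n_vertices * target_mean_degree / 2)
    if m > n_vertices * (n_vertices - 1) // 2:
        raise ValueError("mean degree too large for a simple graph")
    rng = np.random.default_rng(seed)
    base = erdos_renyi_network(n_vertices, m, seed=int(rng.integers(2**31)))
    edges = {tuple(e) for e in base.edges}
    verts = list(base.vertices)
    adj: dict[str, set[str]] = {v: set() for v in verts}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    n_attempts = round(triangle_enrichment * m)
    for _ in range(n_attempts):
        # sample an open wedge j: i - j - k with i, k non-adjacent
        j = verts[int(rng.integers(n_vertices))]
        if len(adj[j]) < 2:
            continue
        nb = sorted(adj[j])
        i, k = (nb[c] for c in rng.choice(len(nb), size=2, replace=False))
        pair = tuple(sorted((i, k)))
        if pair in edges:
            continue
        # remove a random edge not inside the wedge, then close it
        donor = sorted(edges)[int(rng.integers(len(edges)))]
        if set(donor) & {i, j, k}:
            continue
        edges.remove(donor)
        adj[donor[0]].discard(donor[1])
        adj[donor[1]].discard(donor[0])
        edges.add(pair)
        adj[i].add(k)
        adj[k].add(i)

    if directed_fraction == 0:
        return InteractionNetwork.from_edges(sorted(edges), vertices=verts)
    arcs: list[tuple[str, str]] = []
    for u, v in sorted(edges):
        if rng.random() < directed_fraction:
            arcs.append((u, v) if rng.random() < 0.5 else (v, u))
        else:
            arcs.extend([(u, v), (v, u)])
    return InteractionNetwork.from_edges(arcs, directed=True, vertices=verts)


def synthetic_expression(
    spec: SyntheticSpec,
    genes: tuple[str, ...] | None = None,
) -> tuple[ExpressionMatrix, pd.Series, dict]:
    """Two-group negative-binomial count matrix with planted shifts.

    Gene means are log-normal; group B multiplies the planted genes'
    means by ``effect_size`` before sampling, so the shift passes
    through whatever normalisation the pipeline applies downstream.
    Returns (matrix, labels, truth) where truth records the planted
    genes and the spec parameters.
    """
    rng = np.random.default_rng(spec.seed)
    if genes is None:
        width = len(str(spec.n_genes - 1))
        genes = tuple(f"g{i:0{width}d}" for i in range(spec.n_genes))
    else:
        genes = tuple(genes)
    n_genes = len(genes)
    if spec.planted_genes:
        planted = tuple(spec.planted_genes)
        if not set(planted) <= set(genes):
            raise ValueError("planted genes must be a subset of the gene set")
    else:
        picks = rng.choice(n_genes, size=min(spec.n_planted, n_genes), replace=False)
        planted = tuple(sorted(genes[i] for i in picks))
    mu = np.exp(rng.normal(spec.mean_log_mu, spec.sd_log_mu, size=n_genes))
    shift = np.ones(n_genes)
    planted_idx = [genes.index(g) for g in planted]
    shift[planted_idx] = spec.effect_size

    def sample_counts(means: np.ndarray, n_samples: int) -> np.ndarray:
        # NB parameterised by size r = 1/alpha and p = r/(r+mu)
        r = 1.0 / spec.dispersion
        p = r / (r + means)
        return rng.negative_binomial(r, p[:, None], size=(n_genes, n_samples))

    a = sample_counts(mu, spec.n_samples)
    b = sample_counts(mu * shift, spec.n_samples)
    samples = tuple(
        [f"A{i:03d}" for i in range(spec.n_samples)]
        + [f"B{i:03d}" for i in range(spec.n_samples)]
    )
    values = np.concatenate([a, b], axis=1).astype(float)
    matrix = ExpressionMatrix(genes, samples, values)
    labels = pd.Series(
        ["A"] * spec.n_samples + ["B"] * spec.n_samples, index=list(samples), name="group"
    )
    truth = {
        "planted_genes": list(planted),
        "effect_size": spec.effect_size,
        "dispersion": spec.dispersion,
        "n_samples_per_group": spec.n_samples,
        "seed": spec.seed,
    }
    return matrix, labels, truth
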