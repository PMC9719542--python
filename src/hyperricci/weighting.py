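"""Expression-driven stochastic weights on the interaction complex.

A gene-expression vector x (one sample, e.g. one cell) is treated as a
proxy for protein abundance.  The mass-action law makes the propensity
of interaction (i, j) proportional to x_i·x_j; row-normalising over the
neighbours of i yields a Markov transition matrix

    p_ij = x_j / Σ_{k ∈ N(i)} x_k ,

whose stationary distribution π has the detailed-balance closed form
π_i ∝ x_i · Σ_{k ∈ N(i)} x_k on a connected undirected skeleton.  The
entropy rate SR = Σ_i π_i S_i (S_i the local transition entropy)
summarises random-walk heterogeneity.

Geometry enters through a resistance quasimetric: an edge weight is the
inverse of its (symmetrised) interaction probability, so likely
interactions are short.  Vertex weights default to π and face weights
are derived from the boundary edges, giving the strictly positive
weight maps that Forman-Ricci curvature requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.sparse import csgraph

from .complex_builder import InteractionNetwork, SimplicialComplex2D

__all__ = [
    "ExpressionMatrix",
    "TransitionMatrix",
    "StationaryDistribution",
    "WeightedComplex",
    "WeightingConfig",
    "load_expression",
    "normalize_expression",
    "mass_action_transition",
    "stationary_distribution",
    "entropy_rate",
    "geometric_weights",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative genes × samples expression values."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if np.any(vals < 0):
            raise ValueError("expression values must be nonnegative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))

    def sample_vector(self, sample: str) -> dict[str, float]:
        j = self.samples.index(sample)
        return dict(zip(self.genes, self.values[:, j]))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic random-walk matrix on the network skeleton."""

    order: tuple[str, ...]
    P: np.ndarray

    def row(self, v: str) -> np.ndarray:
        return self.P[self.order.index(v)]


@dataclass(frozen=True)
class StationaryDistribution:
    order: tuple[str, ...]
    pi: np.ndarray

    def __getitem__(self, v: str) -> float:
        return float(self.pi[self.order.index(v)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.order, self.pi.astype(float)))


@dataclass(frozen=True)
class WeightingConfig:
    """Options controlling the expression-to-geometry mapping.

    pseudocount
        Added to every expression value after normalisation so the
        mass-action chain is strictly positive everywhere.
    normalization
        ``cpm_log1p`` rescales each sample to one million total counts
        then applies log1p; ``none`` leaves values untouched.
    symmetrization
        How the two directed probabilities of an edge combine into one
        quasimetric length: arithmetic ``mean`` (default), ``min`` or
        ``max``.
    vertex_weight
        ``pi`` uses the stationary probability (default, so curvature
        and its global average share one measure); ``expression`` uses
        the sample's expression value directly.
    face_rule
        Face weight from the three boundary-edge weights:
        ``geometric_mean_squared`` (default, area-like
        (w1·w2·w3)^(2/3)), ``product``, ``mean`` or ``max``.
    """

    pseudocount: float = 1e-3
    normalization: Literal["none", "cpm_log1p"] = "cpm_log1p"
    symmetrization: Literal["mean", "min", "max"] = "mean"
    vertex_weight: Literal["pi", "expression"] = "pi"
    face_rule: Literal["geometric_mean_squared", "product", "mean", "max"] = (
        "geometric_mean_squared"
    )
    normalize_entropy: bool = False


@dataclass(frozen=True)
class WeightedComplex:
    """Strictly positive weights on every cell of a complex, one sample."""

    complex: SimplicialComplex2D
    w_vertex: Mapping[str, float]
    w_edge: Mapping[tuple[str, str], float]
    w_face: Mapping[tuple[str, str, str], float]
    transition: TransitionMatrix
    stationary: StationaryDistribution
    expression: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, wmap in (("vertex", self.w_vertex), ("edge", self.w_edge), ("face", self.w_face)):
            for key, w in wmap.items():
                if not np.isfinite(w) or w <= 0:
                    raise ValueError(f"nonpositive {name} weight {w!r} at {key!r}")


def load_expression(
    path: str | Path,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read expression from TSV/CSV (gene id column first) or MatrixMarket.

    For a ``.mtx`` file, gene and sample identifiers come from the
    companion one-column text files (``genes.tsv`` / ``barcodes.tsv``
    convention).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if sp.issparse(mat):
            mat = mat.toarray()
        if genes_path is None or samples_path is None:
            raise ValueError("MatrixMarket input needs genes and samples files")
        genes = pd.read_csv(genes_path, header=None, sep="\t").iloc[:, 0].astype(str)
        samples = pd.read_csv(samples_path, header=None, sep="\t").iloc[:, 0].astype(str)
        return ExpressionMatrix(tuple(genes), tuple(samples), np.asarray(mat, float))
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix.from_frame(df)


def normalize_expression(
    matrix: ExpressionMatrix,
    method: str = "cpm_log1p",
    pseudocount: float = 1e-3,
) -> ExpressionMatrix:
    """Normalise per sample and add a strictly positive pseudocount.

    ``cpm_log1p`` scales each sample to 1e6 total then applies
    log(1 + x); the pseudocount is added afterwards so every entry is
    strictly positive whenever pseudocount > 0.
    """
    vals = matrix.values
    if method == "cpm_log1p":
        totals = vals.sum(axis=0)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(f"sample {matrix.samples[zero[0]]!r} has zero total expression")
        vals = np.log1p(vals / totals * 1e6)
    elif method != "none":
        raise ValueError(f"unknown normalization method {method!r}")
    return ExpressionMatrix(matrix.genes, matrix.samples, vals + pseudocount)


def mass_action_transition(
    network: InteractionNetwork, x: Mapping[str, float]
) -> TransitionMatrix:
    """Mass-action random-walk transition matrix on the skeleton.

    The propensity of edge (i, j) is x_i·x_j; the x_i factor cancels
    under row normalisation, leaving p_ij = x_j / Σ_{k∈N(i)} x_k over
    the undirected neighbours of i.  Isolated vertices keep an all-zero
    row.
    """
    order = tuple(network.vertices)
    xv = np.array([x[v] for v in order], dtype=float)
    if np.any(xv <= 0) or not np.all(np.isfinite(xv)):
        bad = order[int(np.flatnonzero((xv <= 0) | ~np.isfinite(xv))[0])]
        raise ValueError(f"vertex value must be strictly positive and finite, got x[{bad!r}]")
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    P = np.zeros((n, n))
    adj = network.adjacency()
    for v, nbrs in adj.items():
        if not nbrs:
            continue
        i = idx[v]
        js = np.array(sorted(idx[u] for u in nbrs))
        P[i, js] = xv[js] / xv[js].sum()
    return TransitionMatrix(order=order, P=P)


def _is_connected(adjacency: np.ndarray) -> bool:
    n = adjacency.shape[0]
    comp, _ = csgraph.connected_components(sp.csr_matrix(adjacency), directed=False)
    return comp == 1 or n <= 1


def stationary_distribution(
    transition: TransitionMatrix,
    x: Mapping[str, float] | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> StationaryDistribution:
    """Stationary distribution π with πP = π.

    When the defining expression vector ``x`` is supplied the
    detailed-balance closed form π_i ∝ x_i·Σ_{k∈N(i)} x_k is used;
    otherwise power iteration runs to the requested residual.  The chain
    must be connected (restrict to the largest component first).
    """
    P = transition.P
    support = P > 0
    if not _is_connected(support | support.T):
        raise ValueError(
            "transition matrix is not connected; restrict the network to "
            "its largest component before weighting"
        )
    order = transition.order
    if x is not None:
        xv = np.array([x[v] for v in order], dtype=float)
        neigh_sum = (support * xv[None, :]).sum(axis=1)
        pi = xv * neigh_sum
        pi /= pi.sum()
        return StationaryDistribution(order=order, pi=pi)
    n = len(order)
    pi = np.full(n, 1.0 / n)
    # iterate the lazy chain (P+I)/2: same stationary distribution,
    # aperiodic even on bipartite skeletons
    for _ in range(max_iter):
        nxt = 0.5 * (pi @ P + pi)
        nxt /= nxt.sum()
        if np.abs(nxt - pi).max() < tol:
            pi = nxt
            break
        pi = nxt
    else:
        raise RuntimeError("power iteration failed to converge")
    return StationaryDistribution(order=order, pi=pi)


def entropy_rate(
    transition: TransitionMatrix,
    stationary: StationaryDistribution,
    normalize: bool = False,
) -> float:
    """Entropy rate SR = Σ_i π_i S_i with S_i = −Σ_j p_ij log p_ij.

    Natural logarithm; optionally normalised by log(max degree), the
    maximal local entropy of the skeleton.
    """
    P = transition.P
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    local = -plogp.sum(axis=1)
    sr = float(stationary.pi @ local)
    if normalize:
        max_deg = int((P > 0).sum(axis=1).max())
        sr = sr / np.log(max_deg) if max_deg > 1 else 0.0
    return sr


def _face_weight(ws: tuple[float, float, float], rule: str) -> float:
    if rule == "geometric_mean_squared":
        return float(np.prod(ws) ** (2.0 / 3.0))
    if rule == "product":
        return float(np.prod(ws))
    if rule == "mean":
        return float(np.mean(ws))
    if rule == "max":
        return float(np.max(ws))
    raise ValueError(f"unknown face-weight rule {rule!r}")


def geometric_weights(
    complex: SimplicialComplex2D,
    transition: TransitionMatrix,
    stationary: StationaryDistribution,
    config: WeightingConfig = WeightingConfig(),
    x: Mapping[str, float] | None = None,
) -> WeightedComplex:
    """Resistance-quasimetric weights on vertices, edges and faces.

    Edge weight is the inverse of the symmetrised transition probability
    (default: arithmetic mean of the two directions), vertex weight is
    π_v (or the expression value under ``vertex_weight='expression'``),
    and face weights follow the configured boundary-edge rule.
    """
    idx = {v: i for i, v in enumerate(transition.order)}
    P = transition.P
    w_edge: dict[tuple[str, str], float] = {}
    for u, v in sorted(complex.skeleton.skeleton_edges()):
        pij, pji = P[idx[u], idx[v]], P[idx[v], idx[u]]
        if config.symmetrization == "mean":
            p = 0.5 * (pij + pji)
        elif config.symmetrization == "min":
            p = min(pij, pji)
        elif config.symmetrization == "max":
            p = max(pij, pji)
        else:
            raise ValueError(f"unknown symmetrization {config.symmetrization!r}")
        if p <= 0:
            raise ValueError(f"edge ({u}, {v}) has zero symmetrised probability")
        w_edge[(u, v)] = 1.0 / p
    if config.vertex_weight == "pi":
        w_vertex = {v: float(stationary.pi[i]) for v, i in idx.items()}
    elif config.vertex_weight == "expression":
        if x is None:
            raise ValueError("vertex_weight='expression' requires the expression vector")
        w_vertex = {v: float(x[v]) for v in transition.order}
    else:
        raise ValueError(f"unknown vertex_weight {config.vertex_weight!r}")
    w_face = {
        tri: _face_weight(
            (
                w_edge[(tri[0], tri[1])],
                w_edge[(tri[0], tri[2])],
                w_edge[(tri[1], tri[2])],
            ),
            config.face_rule,
        )
        for tri in sorted(complex.faces)
    }
    return WeightedComplex(
        complex=complex,
        w_vertex=w_vertex,
        w_edge=w_edge,
        w_face=w_face,
        transition=transition,
        stationary=stationary,
        expression=dict(x) if x is not None else {},
    )
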