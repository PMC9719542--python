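"""Construction of the 1D graph skeleton and the 2D simplicial complex.

A protein-interaction network is modelled at two levels: the ordinary
graph ``G = (V, E)`` of pairwise interactions, and a 2-dimensional
simplicial complex ``C = (V, E, F)`` whose faces ``F`` are triangles of
mutually interacting proteins.  In a directed network a triangle
qualifies as a face when its three arcs can be arranged as a feedforward
loop (one regulator driving a target directly and through an
intermediary) or a feedback loop (a directed 3-cycle); in an undirected
network every triangle is a face.

The module also provides topological summaries (Euler characteristic,
edge/face degree distributions, log-log power-law fits) and an
Erdős-Rényi G(n, m) reference generator for comparison against randomly
organised networks of identical size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "SimplicialComplex2D",
    "TopologySummary",
    "DegreeDistribution",
    "PowerLawFit",
    "load_interaction_network",
    "restrict_network",
    "enumerate_faces",
    "build_complex",
    "count_triangles",
    "topology_summary",
    "degree_distribution",
    "fit_power_law",
    "erdos_renyi_network",
]

# orientation classes of a face
FEEDFORWARD = "feedforward"
FEEDBACK = "feedback"
UNDIRECTED = "undirected"


class ConfigurationError(ValueError):
    """Raised when input options are inconsistent with the data."""


@dataclass(frozen=True)
class InteractionNetwork:
    """A simple interaction network: vertices, edges and optional scores.

    ``edges`` holds ordered pairs when ``directed`` is true and
    lexicographically sorted pairs otherwise.  Self-loops are never
    stored; at most one edge exists per ordered pair.  ``score`` maps an
    edge to its integer confidence (STRING convention, 0-1000) and may
    be empty when scores are absent.
    """

    vertices: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    score: Mapping[tuple[str, str], int] = field(default_factory=dict)
    directed: bool = False

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}-{v!r} is not allowed")
            if u not in vset or v not in vset:
                raise ValueError(f"edge endpoint missing from vertices: ({u!r}, {v!r})")
            if not self.directed and u > v:
                raise ValueError(f"undirected edge {u, v} must be stored sorted")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        """Number of skeleton edges (reciprocal arcs collapse to one)."""
        return len(self.skeleton_edges())

    def skeleton_edges(self) -> frozenset[tuple[str, str]]:
        """Undirected edge set: each arc collapsed to a sorted pair."""
        return frozenset(tuple(sorted(e)) for e in self.edges)

    def arcs(self) -> frozenset[tuple[str, str]]:
        """Directed arcs; for an undirected network both directions."""
        if self.directed:
            return self.edges
        return frozenset(
            itertools.chain.from_iterable(((u, v), (v, u)) for u, v in self.edges)
        )

    def adjacency(self) -> dict[str, set[str]]:
        """Undirected neighbour sets over the skeleton."""
        adj: dict[str, set[str]] = {v: set() for v in self.vertices}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g: nx.Graph = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.vertices)
        for e in self.edges:
            g.add_edge(*e, score=self.score.get(e))
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        directed: bool = False,
        score: Mapping[tuple[str, str], int] | None = None,
        vertices: Iterable[str] = (),
    ) -> "InteractionNetwork":
        """Build a network from an edge iterable, dropping self-loops."""
        norm = {}
        score = dict(score or {})
        for u, v in edges:
            if u == v:
                continue
            key = (u, v) if directed else tuple(sorted((u, v)))
            s = score.get((u, v), score.get(key))
            if key in norm:
                if s is not None:
                    norm[key] = max(norm[key] or 0, s)
            else:
                norm[key] = s
        verts = tuple(sorted(set(itertools.chain.from_iterable(norm)) | set(vertices)))
        scores = {e: s for e, s in norm.items() if s is not None}
        return cls(vertices=verts, edges=frozenset(norm), score=scores, directed=directed)


@dataclass(frozen=True)
class SimplicialComplex2D:
    """A 2-dimensional simplicial complex over an interaction network.

    ``faces`` maps each sorted vertex triple to its orientation class
    (``feedforward``, ``feedback`` or ``undirected``).  Incidence maps
    relate edges and vertices to the faces containing them.
    """

    skeleton: InteractionNetwork
    faces: Mapping[tuple[str, str, str], str]
    edge_faces: Mapping[tuple[str, str], frozenset[tuple[str, str, str]]]
    vertex_faces: Mapping[str, frozenset[tuple[str, str, str]]]

    @property
    def n_vertices(self) -> int:
        return self.skeleton.n_vertices

    @property
    def n_edges(self) -> int:
        return self.skeleton.n_edges

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def faces_of_edge(self, e: tuple[str, str]) -> frozenset[tuple[str, str, str]]:
        return self.edge_faces.get(tuple(sorted(e)), frozenset())

    def faces_of_vertex(self, v: str) -> frozenset[tuple[str, str, str]]:
        return self.vertex_faces.get(v, frozenset())


@dataclass(frozen=True)
class TopologySummary:
    n_vertices: int
    n_edges: int
    n_faces: int

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def to_dict(self) -> dict[str, int]:
        return {
            "n_vertices": self.n_vertices,
            "n_edges": self.n_edges,
            "n_faces": self.n_faces,
            "euler_characteristic": self.euler_characteristic,
        }


@dataclass(frozen=True)
class DegreeDistribution:
    """Histogram of per-vertex edge or face degrees with probabilities."""

    kind: str  # "edge" or "face"
    counts: Mapping[int, int]

    @property
    def probabilities(self) -> dict[int, float]:
        total = sum(self.counts.values())
        return {k: c / total for k, c in sorted(self.counts.items())}

    def to_frame(self) -> pd.DataFrame:
        probs = self.probabilities
        return pd.DataFrame(
            {
                "k": sorted(self.counts),
                "count": [self.counts[k] for k in sorted(self.counts)],
                "P_k": [probs[k] for k in sorted(self.counts)],
            }
        )


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log P(k) = log a + b log k over bins with P(k) > 0."""

    intercept_log_a: float
    exponent_b: float
    r_squared: float
    n_points: int


def load_interaction_network(
    path: str | Path,
    score_column: str | None = None,
    cutoff: int = 0,
    directed: bool = False,
    alias_path: str | Path | None = None,
) -> InteractionNetwork:
    """Read an edge-list file into an :class:`InteractionNetwork`.

    Accepts STRING ``protein.links``-style files (space- or
    tab-delimited, header row, two identifier columns plus score
    columns) and plain 2-3 column edge lists.  Rows with
    ``score < cutoff`` and self-loops are dropped; duplicate pairs keep
    the maximum score.  An optional two-column alias table remaps
    identifiers (e.g. STRING protein IDs to gene symbols); rows with
    unmapped identifiers are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two identifier columns")
    cols = list(df.columns)
    if cutoff > 0:
        if score_column is None or score_column not in cols:
            raise ConfigurationError(
                f"score column {score_column!r} required for cutoff {cutoff} "
                f"but not found in {cols}"
            )
    bad = df[df.iloc[:, 0].isna() | df.iloc[:, 1].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed row at line {bad.index[0] + 2}")

    u = df.iloc[:, 0].astype(str)
    v = df.iloc[:, 1].astype(str)
    if score_column is not None and score_column in cols:
        try:
            scores = df[score_column].astype(float).astype(int)
        except ValueError as exc:
            line = int(pd.to_numeric(df[score_column], errors="coerce").isna().idxmax()) + 2
            raise ValueError(f"{path}: malformed score at line {line}") from exc
    else:
        scores = pd.Series([None] * len(df))

    if alias_path is not None:
        alias = pd.read_csv(alias_path, sep=None, engine="python", dtype=str, header=None)
        mapping = dict(zip(alias.iloc[:, 0], alias.iloc[:, 1]))
        mapped = u.isin(mapping) & v.isin(mapping)
        n_drop = int((~mapped).sum())
        if n_drop:
            logger.info("dropped %d rows with unmapped identifiers", n_drop)
        u, v, scores = u[mapped].map(mapping), v[mapped].map(mapping), scores[mapped]

    edges: list[tuple[str, str]] = []
    score_map: dict[tuple[str, str], int] = {}
    n_loops = n_cut = 0
    for a, b, s in zip(u, v, scores):
        if a == b:
            n_loops += 1
            continue
        if s is not None and cutoff > 0 and s < cutoff:
            n_cut += 1
            continue
        edges.append((a, b))
        if s is not None:
            key = (a, b) if directed else tuple(sorted((a, b)))
            score_map[key] = max(score_map.get(key, 0), int(s))
    if n_loops:
        logger.info("dropped %d self-loop rows", n_loops)
    if n_cut:
        logger.info("dropped %d edges below score cutoff %d", n_cut, cutoff)
    return InteractionNetwork.from_edges(edges, directed=directed, score=score_map)


def restrict_network(
    network: InteractionNetwork,
    genes: Iterable[str],
    keep_largest_component: bool = True,
) -> InteractionNetwork:
    """Restrict a network to a gene universe (e.g. the measured genes).

    Optionally retains only the largest (weakly) connected component of
    the restriction, which the random-walk weighting requires.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    keep = set(network.vertices) & genes
    if not keep:
        raise ValueError("no overlap between network vertices and the gene set")
    edges = [e for e in network.edges if e[0] in keep and e[1] in keep]
    sub = InteractionNetwork.from_edges(
        edges, directed=network.directed, score=network.score, vertices=keep
    )
    if keep_largest_component:
        g = sub.to_networkx()
        comps = (
            nx.weakly_connected_components(g) if sub.directed else nx.connected_components(g)
        )
        largest = max(comps, key=lambda c: (len(c), sorted(c)))
        edges = [e for e in sub.edges if e[0] in largest]
        sub = InteractionNetwork.from_edges(
            edges, directed=sub.directed, score=sub.score, vertices=largest
        )
    n_lost = network.n_vertices - sub.n_vertices
    if n_lost:
        logger.info("restriction discarded %d of %d vertices", n_lost, network.n_vertices)
    return sub


def _classify_triangle(
    triple: tuple[str, str, str], arcs: frozenset[tuple[str, str]]
) -> str:
    """Orientation class of a triangle whose three pairs are all linked.

    Feedback takes precedence: a triple is feedback if any assignment of
    the available arc directions closes a directed 3-cycle, otherwise
    feedforward (every tournament on three vertices is either cyclic or
    transitive, so both-pattern coverage is exhaustive).
    """
    a, b, c = triple
    cyc1 = (a, b) in arcs and (b, c) in arcs and (c, a) in arcs
    cyc2 = (a, c) in arcs and (c, b) in arcs and (b, a) in arcs
    return FEEDBACK if (cyc1 or cyc2) else FEEDFORWARD


def enumerate_faces(network: InteractionNetwork) -> dict[tuple[str, str, str], str]:
    """Enumerate oriented triangular faces of a network.

    Returns a map from each sorted vertex triple to its orientation
    class.  For a directed network a triple is a face when all three
    unordered pairs carry at least one arc; it is labelled feedback if
    the arcs admit a directed 3-cycle and feedforward otherwise.  For an
    undirected network every triangle is a face.

    The enumeration intersects neighbour sets along a degree ordering so
    each triangle is visited exactly once.
    """
    adj = network.adjacency()
    # degree ordering bounds the intersection work by the smaller
    # neighbourhood of each edge
    rank = {
        v: i
        for i, v in enumerate(
            sorted(network.vertices, key=lambda v: (len(adj[v]), v))
        )
    }
    arcs = network.arcs() if network.directed else None
    faces: dict[tuple[str, str, str], str] = {}
    for u in sorted(network.vertices):
        higher_u = {w for w in adj[u] if rank[w] > rank[u]}
        for v in higher_u:
            for w in adj[v] & higher_u:
                if rank[w] > rank[v]:
                    triple = tuple(sorted((u, v, w)))
                    if arcs is None:
                        faces[triple] = UNDIRECTED
                    else:
                        faces[triple] = _classify_triangle(triple, arcs)
    return faces


def build_complex(network: InteractionNetwork) -> SimplicialComplex2D:
    """Promote a network to its 2D simplicial complex.

    The skeleton is preserved verbatim; ignoring the faces recovers the
    1D graph model exactly.
    """
    faces = enumerate_faces(network)
    edge_faces: dict[tuple[str, str], set] = {}
    vertex_faces: dict[str, set] = {}
    for tri in faces:
        a, b, c = tri
        for e in ((a, b), (a, c), (b, c)):
            edge_faces.setdefault(e, set()).add(tri)
        for v in tri:
            vertex_faces.setdefault(v, set()).add(tri)
    return SimplicialComplex2D(
        skeleton=network,
        faces=faces,
        edge_faces={e: frozenset(fs) for e, fs in edge_faces.items()},
        vertex_faces={v: frozenset(fs) for v, fs in vertex_faces.items()},
    )


def count_triangles(network: InteractionNetwork) -> int:
    """Count triangles of the undirected skeleton via sparse algebra.

    Uses trace-free counting ``sum(A² ∘ A) / 6`` on the boolean
    adjacency matrix, which scales to proteome-wide networks where
    explicit face enumeration is unnecessary.
    """
    verts = {v: i for i, v in enumerate(network.vertices)}
    edges = network.skeleton_edges()
    if not edges:
        return 0
    rows = np.fromiter((verts[u] for u, v in edges), dtype=np.int32, count=len(edges))
    cols = np.fromiter((verts[v] for u, v in edges), dtype=np.int32, count=len(edges))
    n = len(verts)
    a = sp.coo_matrix(
        (np.ones(2 * len(edges), dtype=np.int64), (np.r_[rows, cols], np.r_[cols, rows])),
        shape=(n, n),
    ).tocsr()
    return int((a @ a).multiply(a).sum() // 6)


def topology_summary(complex: SimplicialComplex2D) -> TopologySummary:
    """Vertex/edge/face counts and the Euler characteristic χ = |V|−|E|+|F|."""
    return TopologySummary(
        n_vertices=complex.n_vertices,
        n_edges=complex.n_edges,
        n_faces=complex.n_faces,
    )


def degree_distribution(complex: SimplicialComplex2D, kind: str = "edge") -> DegreeDistribution:
    """Histogram per-vertex edge degree k_e or face degree k_f.

    Edge degree counts distinct neighbours over the undirected skeleton
    (in- and out-edges to the same neighbour collapse); face degree
    counts incident triangles.
    """
    if kind not in ("edge", "face"):
        raise ValueError(f"kind must be 'edge' or 'face', got {kind!r}")
    if kind == "edge":
        adj = complex.skeleton.adjacency()
        degrees = [len(adj[v]) for v in complex.skeleton.vertices]
    else:
        if not complex.faces:
            logger.warning("face-degree distribution requested on a face-free complex")
        degrees = [
            len(complex.faces_of_vertex(v)) for v in complex.skeleton.vertices
        ]
    counts: dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    return DegreeDistribution(kind=kind, counts=counts)


def fit_power_law(distribution: DegreeDistribution) -> PowerLawFit:
    """Fit P(k) ≈ a·k^b by OLS on the log-log transformed histogram.

    Only unit-width bins with k > 0 and P(k) > 0 enter the fit.  A
    perfectly flat distribution has zero regression variance; its r² is
    reported as 0 by contract.
    """
    probs = distribution.probabilities
    pts = [(k, p) for k, p in probs.items() if k > 0 and p > 0]
    if len(pts) < 3:
        raise ValueError(f"power-law fit needs >= 3 usable bins, got {len(pts)}")
    logk = np.log([k for k, _ in pts])
    logp = np.log([p for _, p in pts])
    b, log_a = np.polyfit(logk, logp, 1)
    resid = logp - (log_a + b * logk)
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    # a flat distribution has no variance to explain: r² = 0 by contract
    degenerate = ss_tot <= 1e-14 * max(1.0, float(np.mean(logp**2))) * len(pts)
    r2 = 0.0 if degenerate else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(
        intercept_log_a=float(log_a),
        exponent_b=float(b),
        r_squared=max(0.0, min(1.0, r2)),
        n_points=len(pts),
    )


def erdos_renyi_network(
    n_vertices: int, n_edges: int, seed: int, directed: bool = False
) -> InteractionNetwork:
    """Uniform G(n, m) random network with exactly ``n_edges`` edges.

    Vertex labels are zero-padded integers so ordering is deterministic.
    """
    max_edges = n_vertices * (n_vertices - 1)
    if not directed:
        max_edges //= 2
    if n_edges > max_edges:
        raise ValueError(
            f"{n_edges} edges infeasible for a simple "
            f"{'directed ' if directed else ''}graph on {n_vertices} vertices"
        )
    g = nx.gnm_random_graph(n_vertices, n_edges, seed=seed, directed=directed)
    width = len(str(n_vertices - 1))
    name = {i: f"v{i:0{width}d}" for i in g.nodes}
    edges = [(name[u], name[v]) for u, v in g.edges]
    return InteractionNetwork.from_edges(
        edges, directed=directed, vertices=name.values()
    )


def expected_er_triangles(n_vertices: int, n_edges: int) -> float:
    """Analytic expected triangle count of G(n, m): C(n,3)·(m/C(n,2))³."""
    p = n_edges / math.comb(n_vertices, 2)
    return math.comb(n_vertices, 3) * p**3
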