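"""Forman-Ricci curvature on weighted 2D simplicial complexes.

Forman's combinatorial Ricci curvature of an edge e with weight w(e),
incident faces f > e, endpoint vertices v < e and parallel edges
e_i ∥ e is

    F(e) = w(e) [ Σ_{f>e} w(e)/w(f) + Σ_{v<e} w(v)/w(e)
                  − Σ_{e_i∥e} | Σ_{f>e,e_i} √(w(e)w(e_i))/w(f)
                               − Σ_{v<e,e_i} w(v)/√(w(e)w(e_i)) | ]

where an edge is parallel to e when it shares a face or a vertex with e
but not both.  On a triangle complex two edges of a common face always
share a vertex, so parallel edges are exactly the vertex-sharing edges
with no common face and their shared-face term vanishes.  Dropping all
face terms gives the 1D graph restriction

    F(e) = w(e) [ Σ_{v<e} w(v)/w(e)
                  − Σ_{e_i∥e} Σ_{v<e,e_i} w(v)/√(w(e)w(e_i)) ] ,

with parallel meaning simply "shares a vertex".  With unit weights the
1D form collapses to the familiar 4 − deg(u) − deg(v).

Edge curvature contracts to vertices, F(v) = (1/deg v) Σ_{e∼v} F(e),
and to a single per-sample scalar via the random-walk stationary
distribution, F_GA = Σ_i π_i F(v_i).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

from .complex_builder import SimplicialComplex2D
from .weighting import StationaryDistribution, WeightedComplex

logger = logging.getLogger(__name__)

__all__ = [
    "CurvatureResult",
    "CurvatureEngine",
    "parallel_edges",
    "forman_ricci_2d",
    "forman_ricci_1d",
    "vertex_curvature",
    "global_average_curvature",
    "curvature_pipeline",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class CurvatureResult:
    """Per-edge, per-vertex and global curvature of one weighted sample."""

    model: str  # "1d" or "2d"
    edge_curvature: Mapping[Edge, float]
    vertex_curvature: Mapping[str, float]
    global_average: float
    entropy: float


def parallel_edges(complex: SimplicialComplex2D, e: Edge) -> set[Edge]:
    """Edges sharing a face or a vertex with ``e`` — but not both."""
    e = tuple(sorted(e))
    edges = complex.skeleton.skeleton_edges()
    if e not in edges:
        raise ValueError(f"edge {e!r} not in complex")
    faces_e = complex.faces_of_edge(e)
    out: set[Edge] = set()
    for ei in edges:
        if ei == e:
            continue
        shares_vertex = bool(set(e) & set(ei))
        shares_face = bool(faces_e & complex.faces_of_edge(ei))
        if shares_vertex != shares_face:
            out.add(ei)
    return out


def _check_weights(weighted: WeightedComplex, e: Edge) -> None:
    if weighted.w_edge[e] <= 0:
        raise ValueError(f"nonpositive weight on edge {e!r}")


def forman_ricci_2d(weighted: WeightedComplex, e: Edge) -> float:
    """Forman-Ricci curvature of one edge, faces included."""
    e = tuple(sorted(e))
    cx = weighted.complex
    we = weighted.w_edge[e]
    _check_weights(weighted, e)
    faces_e = cx.faces_of_edge(e)
    total = sum(we / weighted.w_face[f] for f in sorted(faces_e))
    total += sum(weighted.w_vertex[v] / we for v in e)
    for ei in sorted(parallel_edges(cx, e)):
        wei = weighted.w_edge[ei]
        shared_faces = faces_e & cx.faces_of_edge(ei)
        face_term = sum(math.sqrt(we * wei) / weighted.w_face[f] for f in sorted(shared_faces))
        vertex_term = sum(
            weighted.w_vertex[v] / math.sqrt(we * wei) for v in sorted(set(e) & set(ei))
        )
        total -= abs(face_term - vertex_term)
    return we * total


def forman_ricci_1d(weighted: WeightedComplex, e: Edge) -> float:
    """Graph Forman-Ricci curvature of one edge, all face terms dropped."""
    e = tuple(sorted(e))
    we = weighted.w_edge[e]
    _check_weights(weighted, e)
    total = sum(weighted.w_vertex[v] / we for v in e)
    for ei in sorted(weighted.complex.skeleton.skeleton_edges()):
        if ei == e:
            continue
        shared = set(e) & set(ei)
        if shared:
            wei = weighted.w_edge[ei]
            total -= sum(weighted.w_vertex[v] / math.sqrt(we * wei) for v in sorted(shared))
    return we * total


class CurvatureEngine:
    """Precomputed incidence structure for repeated per-sample evaluation.

    Building the parallel-edge lists once per complex makes scanning
    thousands of expression samples cheap: per sample only the weights
    change, not the combinatorics.
    """

    def __init__(self, complex: SimplicialComplex2D):
        self.complex = complex
        adj = complex.skeleton.adjacency()
        self.edges: list[Edge] = sorted(complex.skeleton.skeleton_edges())
        incident: dict[str, list[Edge]] = {v: [] for v in complex.skeleton.vertices}
        for e in self.edges:
            incident[e[0]].append(e)
            incident[e[1]].append(e)
        self.incident = incident
        # per edge: vertex-sharing neighbours as (other edge, shared vertex)
        self.vertex_neighbours: dict[Edge, list[tuple[Edge, str]]] = {}
        # 2D parallels: vertex-sharing neighbours with no common face
        self.parallel_2d: dict[Edge, list[tuple[Edge, str]]] = {}
        for e in self.edges:
            u, v = e
            nbrs = [(ei, u) for ei in incident[u] if ei != e]
            nbrs += [(ei, v) for ei in incident[v] if ei != e]
            nbrs.sort()
            self.vertex_neighbours[e] = nbrs
            fe = complex.faces_of_edge(e)
            self.parallel_2d[e] = [
                (ei, s) for ei, s in nbrs if not (fe & complex.faces_of_edge(ei))
            ]
        del adj

    def edge_curvatures(self, weighted: WeightedComplex, model: str) -> dict[Edge, float]:
        if model not in ("1d", "2d"):
            raise ValueError(f"model must be '1d' or '2d', got {model!r}")
        wv, we_map, wf = weighted.w_vertex, weighted.w_edge, weighted.w_face
        out: dict[Edge, float] = {}
        for e in self.edges:
            we = we_map[e]
            total = (wv[e[0]] + wv[e[1]]) / we
            if model == "2d":
                for f in sorted(self.complex.faces_of_edge(e)):
                    total += we / wf[f]
                parallels = self.parallel_2d[e]
            else:
                parallels = self.vertex_neighbours[e]
            for ei, shared in parallels:
                total -= wv[shared] / math.sqrt(we * we_map[ei])
            out[e] = we * total
        return out


def vertex_curvature(
    edge_curvature: Mapping[Edge, float], complex: SimplicialComplex2D
) -> dict[str, float]:
    """Contract edge curvature onto vertices: the mean over incident edges."""
    sums: dict[str, float] = {}
    degs: dict[str, int] = {}
    for (u, v), f in sorted(edge_curvature.items()):
        for w in (u, v):
            sums[w] = sums.get(w, 0.0) + f
            degs[w] = degs.get(w, 0) + 1
    isolated = set(complex.skeleton.vertices) - set(sums)
    if isolated:
        logger.info("excluding %d isolated vertices from vertex curvature", len(isolated))
    return {v: sums[v] / degs[v] for v in sorted(sums)}


def global_average_curvature(
    vertex_curv: Mapping[str, float], stationary: StationaryDistribution
) -> float:
    """π-weighted global average F_GA = Σ_i π_i F(v_i)."""
    if set(vertex_curv) != set(stationary.order):
        raise ValueError("vertex curvature and stationary distribution cover different vertices")
    pi = stationary.as_dict()
    return float(sum(pi[v] * f for v, f in sorted(vertex_curv.items())))


def curvature_pipeline(
    weighted: WeightedComplex,
    model: str = "2d",
    engine: CurvatureEngine | None = None,
    normalize_entropy: bool = False,
) -> CurvatureResult:
    """Edge → vertex → global curvature of one weighted sample.

    Pass a prebuilt :class:`CurvatureEngine` when evaluating many
    samples on the same complex.
    """
    from .weighting import entropy_rate  # local import avoids cycle at module load

    model = model.lower()
    if engine is None:
        engine = CurvatureEngine(weighted.complex)
    edge_curv = engine.edge_curvatures(weighted, model)
    vert_curv = vertex_curvature(edge_curv, weighted.complex)
    fga = global_average_curvature(vert_curv, weighted.stationary)
    sr = entropy_rate(weighted.transition, weighted.stationary, normalize=normalize_entropy)
    return CurvatureResult(
        model=model,
        edge_curvature=edge_curv,
        vertex_curvature=vert_curv,
        global_average=fga,
        entropy=sr,
    )
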