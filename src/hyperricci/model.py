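"""Model/results interface tying the pipeline together.

:class:`NetworkCurvatureModel` couples an interaction network with a
genes × samples expression matrix; ``fit()`` builds the simplicial
complex, weights it per sample by the mass-action random walk, and
evaluates Forman-Ricci curvature, returning a
:class:`NetworkCurvatureResults` object that carries per-edge,
per-vertex and global curvature together with entropy, and offers
differential testing and enrichment downstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import complex_builder as cb
from . import curvature as curv
from . import diff_stats as ds
from . import weighting as wt

__all__ = ["NetworkCurvatureModel", "NetworkCurvatureResults"]


class NetworkCurvatureModel:
    """Weighted-complex curvature model of a set of expression samples.

    Parameters
    ----------
    network
        Interaction network (directed or undirected).  It is restricted
        to the genes present in the expression matrix and to its
        largest connected component, which the stationary distribution
        requires.
    expression
        Raw nonnegative genes × samples matrix.
    config
        Weighting options (normalisation, pseudocount, symmetrisation,
        vertex-weight source, face-weight rule).
    """

    def __init__(
        self,
        network: cb.InteractionNetwork,
        expression: wt.ExpressionMatrix,
        config: wt.WeightingConfig = wt.WeightingConfig(),
    ):
        self.config = config
        self.network = cb.restrict_network(
            network, set(expression.genes), keep_largest_component=True
        )
        keep = [g in set(self.network.vertices) for g in expression.genes]
        genes = tuple(g for g, k in zip(expression.genes, keep) if k)
        self.expression = wt.ExpressionMatrix(
            genes, expression.samples, expression.values[np.asarray(keep)]
        )
        self.complex = cb.build_complex(self.network)
        self._engine = curv.CurvatureEngine(self.complex)
        self._normalized = wt.normalize_expression(
            self.expression, method=config.normalization, pseudocount=config.pseudocount
        )

    @classmethod
    def from_files(
        cls,
        edges_path: str | Path,
        expression_path: str | Path,
        score_column: str | None = None,
        cutoff: int = 0,
        directed: bool = False,
        config: wt.WeightingConfig = wt.WeightingConfig(),
    ) -> "NetworkCurvatureModel":
        network = cb.load_interaction_network(
            edges_path, score_column=score_column, cutoff=cutoff, directed=directed
        )
        expression = wt.load_expression(expression_path)
        return cls(network, expression, config=config)

    def weight_sample(self, sample: str) -> wt.WeightedComplex:
        """Weighted complex of one sample under the model's config."""
        x = self._normalized.sample_vector(sample)
        transition = wt.mass_action_transition(self.network, x)
        stationary = wt.stationary_distribution(transition, x=x)
        return wt.geometric_weights(
            self.complex, transition, stationary, config=self.config, x=x
        )

    def fit(self, model: str = "both", samples: Iterable[str] | None = None) -> "NetworkCurvatureResults":
        """Evaluate curvature for every sample.

        ``model`` selects the 1D graph form, the 2D complex form, or
        both.
        """
        models = ("1d", "2d") if model == "both" else (model.lower(),)
        for m in models:
            if m not in ("1d", "2d"):
                raise ValueError(f"model must be '1d', '2d' or 'both', got {model!r}")
        samples = list(samples) if samples is not None else list(self.expression.samples)
        per_model: dict[str, list[curv.CurvatureResult]] = {m: [] for m in models}
        for s in samples:
            weighted = self.weight_sample(s)
            for m in models:
                per_model[m].append(
                    curv.curvature_pipeline(
                        weighted, m, engine=self._engine,
                        normalize_entropy=self.config.normalize_entropy,
                    )
                )
        return NetworkCurvatureResults(self, tuple(samples), per_model)


class NetworkCurvatureResults:
    """Fitted curvature values across samples, with summary and tests."""

    def __init__(
        self,
        model: NetworkCurvatureModel,
        samples: tuple[str, ...],
        per_model: Mapping[str, list[curv.CurvatureResult]],
    ):
        self.model = model
        self.samples = samples
        self._results = {m: list(rs) for m, rs in per_model.items()}
        self.models = tuple(sorted(self._results))

    def _check(self, model: str) -> str:
        model = model.lower()
        if model not in self._results:
            raise KeyError(f"model {model!r} was not fitted; have {self.models}")
        return model

    def edge_curvature(self, model: str = "2d") -> pd.DataFrame:
        """Edges × samples frame of Forman-Ricci values."""
        m = self._check(model)
        results = self._results[m]
        edges = sorted(results[0].edge_curvature)
        data = {
            s: [r.edge_curvature[e] for e in edges]
            for s, r in zip(self.samples, results)
        }
        idx = pd.Index([f"{u}|{v}" for u, v in edges], name="edge")
        return pd.DataFrame(data, index=idx)

    def vertex_curvature(self, model: str = "2d") -> pd.DataFrame:
        """Genes × samples frame of contracted vertex curvature."""
        m = self._check(model)
        results = self._results[m]
        genes = sorted(results[0].vertex_curvature)
        data = {
            s: [r.vertex_curvature[g] for g in genes]
            for s, r in zip(self.samples, results)
        }
        return pd.DataFrame(data, index=pd.Index(genes, name="gene"))

    def global_average(self, model: str = "2d") -> pd.Series:
        m = self._check(model)
        return pd.Series(
            [r.global_average for r in self._results[m]], index=list(self.samples),
            name=f"F_GA_{m}",
        )

    def entropy(self) -> pd.Series:
        """Per-sample entropy rate of the mass-action random walk."""
        m = self.models[0]
        return pd.Series(
            [r.entropy for r in self._results[m]], index=list(self.samples), name="SR"
        )

    def differential(
        self, labels: pd.Series, group_a: str, group_b: str,
        model: str = "2d", alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Per-gene differential vertex curvature between two groups."""
        vc = self.vertex_curvature(model)
        a = vc.loc[:, [s for s in vc.columns if labels.get(s) == group_a]]
        b = vc.loc[:, [s for s in vc.columns if labels.get(s) == group_b]]
        return ds.differential_table(a, b, alpha=alpha)

    def summary(self) -> str:
        """Plain-text overview in the spirit of a regression summary."""
        cx = self.model.complex
        topo = cb.topology_summary(cx)
        lines = [
            "Network curvature model",
            "=" * 55,
            f"vertices: {topo.n_vertices}   edges: {topo.n_edges}   "
            f"faces: {topo.n_faces}   chi: {topo.euler_characteristic}",
            f"samples fitted: {len(self.samples)}   models: {', '.join(self.models)}",
            f"weighting: norm={self.model.config.normalization} "
            f"pc={self.model.config.pseudocount} "
            f"sym={self.model.config.symmetrization} "
            f"w(v)={self.model.config.vertex_weight} "
            f"w(f)={self.model.config.face_rule}",
            "-" * 55,
        ]
        sr = self.entropy()
        lines.append(f"entropy SR: mean {sr.mean():.4f}  sd {sr.std(ddof=0):.4f}")
        for m in self.models:
            ga = self.global_average(m)
            lines.append(
                f"F_GA ({m}): mean {ga.mean():.4f}  sd {ga.std(ddof=0):.4f}  "
                f"min {ga.min():.4f}  max {ga.max():.4f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample global measures: entropy and global curvature."""
        cols = {"SR": self.entropy()}
        for m in self.models:
            cols[f"F_GA_{m}"] = self.global_average(m)
        return pd.DataFrame(cols)
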