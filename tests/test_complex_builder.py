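"""Skeleton and complex construction, topology summaries, ER reference."""

import itertools
import math

import numpy as np
import pytest

import hyperricci as hr
from hyperricci.complex_builder import (
    ConfigurationError,
    expected_er_triangles,
    count_triangles,
)


def write_edges(tmp_path, rows, header="protein1\tprotein2\tcombined_score"):
    p = tmp_path / "edges.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


TOY_ROWS = [
    "a\tb\t900",
    "b\tc\t400",
    "c\td\t150",
    "d\te\t700",
    "e\ta\t950",
]


class TestLoadInteractionNetwork:
    def test_score_cutoff_filters_edges(self, tmp_path):
        p = write_edges(tmp_path, TOY_ROWS)
        net = hr.load_interaction_network(p, score_column="combined_score", cutoff=400)
        assert net.n_edges == 4
        net0 = hr.load_interaction_network(p, score_column="combined_score", cutoff=0)
        assert net0.n_edges == 5

    def test_self_loops_dropped(self, tmp_path):
        p = write_edges(tmp_path, TOY_ROWS + ["a\ta\t999"])
        net = hr.load_interaction_network(p, score_column="combined_score", cutoff=0)
        assert ("a", "a") not in net.edges
        assert net.n_edges == 5

    def test_duplicate_rows_keep_max_score(self, tmp_path):
        p = write_edges(tmp_path, ["a\tb\t300", "b\ta\t800"])
        net = hr.load_interaction_network(p, score_column="combined_score", cutoff=0)
        assert net.score[("a", "b")] == 800

    def test_space_delimited_string_dialect(self, tmp_path):
        p = tmp_path / "links.txt"
        p.write_text("protein1 protein2 combined_score\nx y 700\ny z 200\n")
        net = hr.load_interaction_network(p, score_column="combined_score", cutoff=400)
        assert net.skeleton_edges() == frozenset({("x", "y")})

    def test_missing_file_and_missing_score_column(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            hr.load_interaction_network(tmp_path / "nope.tsv")
        p = write_edges(tmp_path, ["a\tb"], header="protein1\tprotein2")
        with pytest.raises(ConfigurationError):
            hr.load_interaction_network(p, score_column="combined_score", cutoff=400)

    def test_alias_mapping_drops_unmapped(self, tmp_path):
        p = write_edges(tmp_path, ["p1\tp2\t900", "p2\tp3\t900"])
        alias = tmp_path / "alias.tsv"
        alias.write_text("p1\tGENE1\np2\tGENE2\n")
        net = hr.load_interaction_network(p, cutoff=0, alias_path=alias)
        assert net.skeleton_edges() == frozenset({("GENE1", "GENE2")})

    def test_vertex_order_deterministic(self, tmp_path):
        p = write_edges(tmp_path, TOY_ROWS)
        net = hr.load_interaction_network(p, cutoff=0)
        assert net.vertices == tuple(sorted(net.vertices))


class TestRestrictNetwork:
    def setup_method(self):
        self.net = hr.InteractionNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("d", "e")]
        )

    def test_largest_component_kept(self):
        sub = hr.restrict_network(self.net, {"a", "b", "c", "d", "e"}, True)
        assert set(sub.vertices) == {"a", "b", "c"}
        assert sub.n_edges == 2

    def test_plain_intersection(self):
        sub = hr.restrict_network(self.net, {"a", "b"}, False)
        assert sub.skeleton_edges() == frozenset({("a", "b")})

    def test_disjoint_gene_set_errors(self):
        with pytest.raises(ValueError):
            hr.restrict_network(self.net, {"x", "y"}, True)


class TestFaceEnumeration:
    def test_feedforward_and_feedback(self, toys):
        assert hr.enumerate_faces(toys["ffl"]) == {("a", "b", "c"): "feedforward"}
        assert hr.enumerate_faces(toys["fbl"]) == {("a", "b", "c"): "feedback"}

    def test_open_triangle_is_not_a_face(self):
        net = hr.InteractionNetwork.from_edges([("a", "b"), ("b", "c")], directed=True)
        assert hr.enumerate_faces(net) == {}

    def test_undirected_k4_has_four_faces(self):
        k4 = hr.InteractionNetwork.from_edges(itertools.combinations("abcd", 2))
        faces = hr.enumerate_faces(k4)
        assert set(faces) == set(itertools.combinations("abcd", 3))
        assert set(faces.values()) == {"undirected"}

    def test_feedback_precedence_with_reciprocal_arcs(self):
        # all pairs bidirectional: a 3-cycle assignment exists
        arcs = [(u, v) for u, v in itertools.permutations("abc", 2)]
        net = hr.InteractionNetwork.from_edges(arcs, directed=True)
        assert hr.enumerate_faces(net) == {("a", "b", "c"): "feedback"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        verts = [f"v{i}" for i in range(n)]
        arcs = set()
        for _ in range(int(rng.integers(n, 4 * n))):
            i, j = rng.integers(n, size=2)
            if i != j:
                arcs.add((verts[i], verts[j]))
        net = hr.InteractionNetwork.from_edges(sorted(arcs), directed=True)
        faces = hr.enumerate_faces(net)

        # oracle: examine all C(n,3) triples directly against the arc set
        expected = {}
        for tri in itertools.combinations(sorted(net.vertices), 3):
            a, b, c = tri
            pairs_ok = all(
                (u, v) in arcs or (v, u) in arcs
                for u, v in [(a, b), (a, c), (b, c)]
            )
            if not pairs_ok:
                continue
            cyc = ((a, b) in arcs and (b, c) in arcs and (c, a) in arcs) or (
                (a, c) in arcs and (c, b) in arcs and (b, a) in arcs
            )
            expected[tri] = "feedback" if cyc else "feedforward"
        assert faces == expected


class TestComplexAndTopology:
    def test_directed_three_cycle_complex(self, toys):
        cx = hr.build_complex(toys["fbl"])
        assert (cx.n_vertices, cx.n_edges, cx.n_faces) == (3, 3, 1)

    def test_edgeless_network(self):
        net = hr.InteractionNetwork(vertices=("a", "b"), edges=frozenset())
        cx = hr.build_complex(net)
        assert cx.n_faces == 0

    def test_k4_incidence(self):
        k4 = hr.InteractionNetwork.from_edges(itertools.combinations("abcd", 2))
        cx = hr.build_complex(k4)
        assert cx.n_faces == 4
        for e in k4.skeleton_edges():
            assert len(cx.faces_of_edge(e)) == 2

    def test_euler_characteristic_paper_scale_counts(self):
        # proteome-scale component counts, with and without faces
        s2 = hr.TopologySummary(11888, 315130, 10451604)
        assert s2.euler_characteristic == 10148362
        s1 = hr.TopologySummary(11888, 315130, 0)
        assert s1.euler_characteristic == -303242
        assert s1.euler_characteristic - s2.euler_characteristic == -s2.n_faces

    def test_filled_triangle_is_a_disk(self, toys):
        cx = hr.build_complex(toys["filled_triangle"])
        assert hr.topology_summary(cx).euler_characteristic == 1

    def test_chi_difference_is_face_count(self):
        rng = np.random.default_rng(7)
        net = hr.erdos_renyi_network(30, 90, seed=3)
        cx = hr.build_complex(net)
        s = hr.topology_summary(cx)
        chi_1d = s.n_vertices - s.n_edges
        assert chi_1d - s.euler_characteristic == -s.n_faces


class TestDegreeDistributions:
    def test_star_edge_degrees(self, toys):
        cx = hr.build_complex(toys["star5"])
        dist = hr.degree_distribution(cx, kind="edge")
        assert dict(dist.counts) == {5: 1, 1: 5}
        assert abs(sum(dist.probabilities.values()) - 1) < 1e-12

    def test_filled_triangle_face_degrees(self, toys):
        cx = hr.build_complex(toys["filled_triangle"])
        assert dict(hr.degree_distribution(cx, kind="face").counts) == {1: 3}

    def test_k4_face_degrees(self):
        k4 = hr.InteractionNetwork.from_edges(itertools.combinations("abcd", 2))
        cx = hr.build_complex(k4)
        assert dict(hr.degree_distribution(cx, kind="face").counts) == {3: 4}

    def test_face_free_complex_warns_and_zeroes(self, toys):
        cx = hr.build_complex(toys["face_free"])
        dist = hr.degree_distribution(cx, kind="face")
        assert dict(dist.counts) == {0: 4}

    def test_degree_sums(self):
        net = hr.erdos_renyi_network(40, 160, seed=11)
        cx = hr.build_complex(net)
        edge_counts = hr.degree_distribution(cx, "edge").counts
        assert sum(k * c for k, c in edge_counts.items()) == 2 * cx.n_edges
        face_counts = hr.degree_distribution(cx, "face").counts
        assert sum(k * c for k, c in face_counts.items()) == 3 * cx.n_faces
        assert sum(edge_counts.values()) == cx.n_vertices


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        counts = {k: round(1e6 * k**-2.0) for k in range(1, 11)}
        dist = hr.DegreeDistribution(kind="edge", counts=counts)
        fit = hr.fit_power_law(dist)
        assert fit.exponent_b == pytest.approx(-2.0, abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-5)

    def test_flat_distribution_r2_zero(self):
        dist = hr.DegreeDistribution(kind="edge", counts={k: 10 for k in range(1, 11)})
        fit = hr.fit_power_law(dist)
        assert fit.exponent_b == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_matches_independent_ols_on_sampled_degrees(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        degrees = np.round(rng.pareto(2.0, size=2000) + 1).astype(int)
        counts = {int(k): int(c) for k, c in zip(*np.unique(degrees, return_counts=True))}
        fit = hr.fit_power_law(hr.DegreeDistribution(kind="edge", counts=counts))
        total = sum(counts.values())
        pts = [(k, c / total) for k, c in counts.items() if k > 0]
        X = sm.add_constant(np.log([k for k, _ in pts]))
        ref = sm.OLS(np.log([p for _, p in pts]), X).fit()
        assert fit.exponent_b == pytest.approx(ref.params[1], abs=0.05)
        assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-6)

    def test_too_few_bins_errors(self):
        dist = hr.DegreeDistribution(kind="edge", counts={1: 5, 2: 3})
        with pytest.raises(ValueError):
            hr.fit_power_law(dist)


class TestErdosRenyi:
    def test_forced_complete_graph(self):
        net = hr.erdos_renyi_network(5, 10, seed=0)
        assert net.n_edges == 10
        assert count_triangles(net) == 10

    def test_same_seed_reproducible(self):
        a = hr.erdos_renyi_network(50, 200, seed=9)
        b = hr.erdos_renyi_network(50, 200, seed=9)
        assert a.edges == b.edges

    def test_infeasible_edge_count(self):
        with pytest.raises(ValueError):
            hr.erdos_renyi_network(4, 7, seed=0)

    def test_triangle_count_matches_analytic_expectation(self):
        n, m = 400, 3200
        counts = [
            count_triangles(hr.erdos_renyi_network(n, m, seed=s)) for s in range(6)
        ]
        expect = expected_er_triangles(n, m)
        assert abs(np.mean(counts) - expect) < 0.05 * expect

    def test_count_triangles_equals_enumeration(self):
        net = hr.erdos_renyi_network(60, 300, seed=2)
        assert count_triangles(net) == hr.build_complex(net).n_faces
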