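"""Fingerprint comparison: cliques, superposition, Tanimoto index."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from kgs2.fingerprints import Fingerprint, FingerprintNode
from kgs2.similarity import (
    TooLargeComparisonError,
    build_correspondence_graph,
    compare,
    count_overlaps,
    distance_compatible,
    maximal_cliques,
    search_reference,
    similarity_index,
    superimpose,
)


def make_fp(complex_id, coords, labels=None, kinds=None, affinity=None):
    coords = np.asarray(coords, float)
    labels = labels or [f"T{i}" for i in range(len(coords))]
    kinds = kinds or ["ligand"] * len(coords)
    nodes = [
        FingerprintNode(kind=k, label=l, coords=tuple(map(float, c)),
                        anchor=(i,))
        for i, (c, l, k) in enumerate(zip(coords, labels, kinds))
    ]
    return Fingerprint(complex_id=complex_id, nodes=nodes, affinity=affinity)


def _scatter(n, rng, scale=10.0):
    """Random points with no two pairwise distances ratio-compatible by
    accident being likely; just well spread."""
    return rng.uniform(0, scale, size=(n, 3))


class TestDistanceCompatible:
    @pytest.mark.parametrize("d1,d2,expected", [
        (10.0, 9.2, True),   # 10 < 1.1 * 9.2 = 10.12
        (10.0, 9.0, False),  # 10 >= 9.9
        (0.0, 0.0, True),    # equality convention
        (5.0, 5.0, True),
    ])
    def test_ratio_rule(self, d1, d2, expected):
        assert distance_compatible(d1, d2) is expected

    @given(st.floats(0, 100, allow_nan=False),
           st.floats(0, 100, allow_nan=False))
    def test_symmetric(self, d1, d2):
        assert distance_compatible(d1, d2) == distance_compatible(d2, d1)


class TestCorrespondenceGraph:
    def test_self_comparison_has_diagonal_clique(self):
        rng = np.random.default_rng(0)
        fp = make_fp("a", _scatter(6, rng))
        g = build_correspondence_graph(fp, fp)
        diagonal = [(i, i) for i in range(6)]
        for v1, v2 in itertools.combinations(diagonal, 2):
            assert g.graph.has_edge(v1, v2)

    def test_disjoint_labels_give_no_vertices(self):
        rng = np.random.default_rng(1)
        p = make_fp("a", _scatter(3, rng), labels=["X", "Y", "Z"])
        q = make_fp("b", _scatter(3, rng), labels=["U", "V", "W"])
        assert build_correspondence_graph(p, q).graph.number_of_nodes() == 0

    def test_kind_must_match(self):
        p = make_fp("a", [(0, 0, 0)], labels=["GLY"], kinds=["protein"])
        q = make_fp("b", [(0, 0, 0)], labels=["GLY"], kinds=["ligand"])
        assert build_correspondence_graph(p, q).graph.number_of_nodes() == 0

    def test_edges_match_brute_force(self):
        rng = np.random.default_rng(2)
        labels = ["A", "A", "B", "B", "C", "C"]
        p = make_fp("a", _scatter(6, rng), labels=labels)
        q = make_fp("b", _scatter(6, rng), labels=labels)
        corr = build_correspondence_graph(p, q)
        vertices = [(i, j) for i in range(6) for j in range(6)
                    if labels[i] == labels[j]]
        assert set(corr.graph.nodes) == set(vertices)
        for v1, v2 in itertools.combinations(vertices, 2):
            i1, j1 = v1
            i2, j2 = v2
            if i1 == i2 or j1 == j2:
                expected = False
            else:
                d1 = np.linalg.norm(p.nodes[i1].xyz - p.nodes[i2].xyz)
                d2 = np.linalg.norm(q.nodes[j1].xyz - q.nodes[j2].xyz)
                expected = distance_compatible(d1, d2)
            assert corr.graph.has_edge(v1, v2) == expected


def _brute_force_max_clique_size(g: nx.Graph) -> int:
    nodes = list(g.nodes)
    best = 1 if nodes else 0
    for r in range(len(nodes), 1, -1):
        for subset in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b)
                   for a, b in itertools.combinations(subset, 2)):
                return r
    return best


class TestMaximalCliques:
    def test_five_cycle(self):
        g = nx.cycle_graph(5)
        cliques = maximal_cliques(g)
        assert all(len(c) == 2 for c in cliques)
        assert len(cliques) == 5

    def test_complete_graph(self):
        cliques = maximal_cliques(nx.complete_graph(4))
        assert cliques == [[0, 1, 2, 3]]

    def test_random_graphs_match_exhaustive(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            g = nx.gnp_random_graph(12, rng.uniform(0.2, 0.8),
                                    seed=int(rng.integers(1 << 31)))
            cliques = maximal_cliques(g)
            assert len(cliques[0]) == _brute_force_max_clique_size(g)

    def test_vertex_cap(self):
        g = nx.empty_graph(10)
        with pytest.raises(TooLargeComparisonError):
            maximal_cliques(g, cap=5)


class TestSuperimpose:
    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(4)
        p = _scatter(8, rng)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-10, 10, size=3)
        q = (p - t) @ R  # so that R @ q + t = p  with q = R.T (p - t)
        transform = superimpose(p, q)
        np.testing.assert_allclose(transform.apply(q), p, atol=1e-9)
        np.testing.assert_allclose(transform.rotation, R, atol=1e-9)

    def test_three_point_rotation_recovery(self):
        p = np.array([[1.0, 0, 0], [0, 2.0, 0], [0, 0, 3.0]])
        R = Rotation.from_euler("z", 0.7).as_matrix()
        q = p @ R  # q = R.T p
        transform = superimpose(p, q)
        np.testing.assert_allclose(transform.rotation, R, atol=1e-9)

    def test_mirror_is_never_a_reflection(self):
        rng = np.random.default_rng(5)
        p = _scatter(6, rng)
        q = p * np.array([-1.0, 1.0, 1.0])  # reflected copy
        transform = superimpose(p, q)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)
        rmsd = np.sqrt(np.mean(np.sum((transform.apply(q) - p) ** 2, axis=1)))
        assert rmsd > 0.1

    def test_two_points_translation_only(self):
        p = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        q = p + np.array([5.0, 5.0, 5.0])
        transform = superimpose(p, q)
        np.testing.assert_allclose(transform.rotation, np.eye(3))
        np.testing.assert_allclose(transform.apply(q), p, atol=1e-12)


class TestCountOverlaps:
    def test_exact_copy_counts_all(self):
        rng = np.random.default_rng(6)
        fp = make_fp("a", _scatter(7, rng))
        corr = build_correspondence_graph(fp, fp)
        from kgs2.similarity import RigidTransform
        n, mapping = count_overlaps(RigidTransform.identity(),
                                    list(corr.graph.nodes),
                                    corr.p_nodes, corr.q_nodes)
        assert n == 7

    def test_displaced_node_not_counted(self):
        rng = np.random.default_rng(7)
        pts = _scatter(6, rng)
        moved = pts.copy()
        moved[0] += [1.5, 0, 0]
        p = make_fp("a", pts)
        q = make_fp("b", moved)
        corr = build_correspondence_graph(p, q)
        from kgs2.similarity import RigidTransform
        n, _ = count_overlaps(RigidTransform.identity(),
                              list(corr.graph.nodes),
                              corr.p_nodes, corr.q_nodes)
        assert n == 5

    def test_conflicting_candidates_count_once(self):
        # two Q nodes of the same label within 1 A of a single P node
        p = make_fp("a", [(0, 0, 0)], labels=["X"])
        q = make_fp("b", [(0.2, 0, 0), (0.3, 0, 0)], labels=["X", "X"])
        corr = build_correspondence_graph(p, q)
        from kgs2.similarity import RigidTransform
        n, mapping = count_overlaps(RigidTransform.identity(),
                                    list(corr.graph.nodes),
                                    corr.p_nodes, corr.q_nodes)
        assert n == 1
        assert mapping == [(0, 0)]  # nearest-first wins


class TestSimilarityIndex:
    def test_half_shared_equal_size(self):
        assert similarity_index(10, 10, 5) == pytest.approx(1 / 3)

    def test_identical_sets(self):
        assert similarity_index(7, 7, 7) == pytest.approx(1.0)

    def test_no_overlap_and_empty(self):
        assert similarity_index(5, 8, 0) == 0.0
        assert similarity_index(0, 0, 0) == 0.0

    def test_overlap_cannot_exceed_sizes(self):
        with pytest.raises(ValueError):
            similarity_index(3, 5, 4)

    @given(st.integers(0, 50), st.integers(0, 50))
    def test_bounded_unit_interval(self, n_p, n_q):
        n_pq = min(n_p, n_q)
        assert 0.0 <= similarity_index(n_p, n_q, n_pq) <= 1.0


class TestCompare:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(8)
        fp = make_fp("a", _scatter(8, rng))
        copy = make_fp("b", [n.coords for n in fp.nodes])
        result = compare(fp, copy)
        assert result.si == pytest.approx(1.0)
        assert result.qualified

    def test_pruned_rigid_copy_arithmetic(self):
        """Two 8-node sets sharing 5 nodes of an 11-node template:
        SI = 5 / (8 + 8 - 5) = 5/11."""
        rng = np.random.default_rng(9)
        template = _scatter(11, rng, scale=12.0)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-5, 5, size=3)
        labels = [f"T{i}" for i in range(11)]
        p = make_fp("a", template[:8], labels=labels[:8])
        q = make_fp("b", template[3:] @ R.T + t, labels=labels[3:])
        result = compare(p, q)
        assert (result.n_p, result.n_q, result.n_pq) == (8, 8, 5)
        assert result.si == pytest.approx(5 / 11)
        assert result.qualified

    def test_four_overlaps_not_qualified(self):
        rng = np.random.default_rng(10)
        template = _scatter(12, rng, scale=12.0)
        labels = [f"T{i}" for i in range(12)]
        p = make_fp("a", template[:8], labels=labels[:8])
        q = make_fp("b", template[4:], labels=labels[4:])
        result = compare(p, q)
        assert result.n_pq == 4
        assert not result.qualified

    def test_symmetry(self, full_library):
        fps = full_library.fingerprints
        pairs = [(fps[0], fps[1]), (fps[0], fps[4]), (fps[2], fps[9])]
        for p, q in pairs:
            fwd = compare(p, q)
            rev = compare(q, p)
            assert fwd.si == pytest.approx(rev.si)
            assert fwd.n_pq == rev.n_pq
            assert (fwd.n_p, fwd.n_q) == (rev.n_q, rev.n_p)

    def test_adding_shared_node_never_decreases_overlap(self):
        rng = np.random.default_rng(11)
        template = _scatter(8, rng, scale=12.0)
        labels = [f"T{i}" for i in range(8)]
        p = make_fp("a", template, labels=labels)
        q = make_fp("b", template, labels=labels)
        base = compare(p, q).n_pq
        extra = rng.uniform(0, 12, size=3)
        p2 = make_fp("a", np.vstack([template, extra]), labels=labels + ["T8"])
        q2 = make_fp("b", np.vstack([template, extra]), labels=labels + ["T8"])
        assert compare(p2, q2).n_pq >= base


class TestSearchReference:
    def test_query_itself_is_excluded(self, full_library):
        fp = full_library.fingerprints[0]
        ref, result = search_reference(fp, full_library.fingerprints)
        assert ref is not None
        assert ref.complex_id != fp.complex_id

    def test_below_cutoff_returns_none(self, full_library):
        fp = full_library.fingerprints[0]
        ref, result = search_reference(fp, full_library.fingerprints,
                                       min_si=1.01)
        assert ref is None and result is None

    def test_planted_best_is_found(self, full_library):
        fp = full_library.fingerprints[2]
        ref, result = search_reference(fp, full_library.fingerprints)
        assert ref.complex_id == full_library.twin_of(fp.complex_id)
        assert result.qualified

    def test_exclude_ids_respected(self, full_library):
        fp = full_library.fingerprints[2]
        twin = full_library.twin_of(fp.complex_id)
        ref, result = search_reference(fp, full_library.fingerprints,
                                       exclude_ids=[twin])
        assert ref is None or ref.complex_id != twin

    def test_empty_library_warns(self, full_library):
        with pytest.warns(UserWarning, match="empty"):
            ref, result = search_reference(full_library.fingerprints[0], [])
        assert ref is None
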