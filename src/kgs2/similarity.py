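"""Fingerprint comparison and reference search.

Two fingerprints P and Q are compared with a correspondence-graph
approach: every same-kind, same-label node pair (p, q) becomes a vertex;
two vertices are joined iff the intra-set distances they imply are
compatible within a ratio (default 1.1). Maximum cliques of this graph
(Bron-Kerbosch with pivoting) give candidate correspondences; each seeds
a rigid (Kabsch) superposition of Q onto P, after which matched node
pairs closer than 1 A count as geometrically overlapped. The solution
with the most overlapped pairs is retained and scored with the Tanimoto
index SI = Npq / (Np + Nq - Npq). A candidate qualifies as a reference
only with at least five overlapped pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from kgs2.fingerprints import Fingerprint, FingerprintNode

__all__ = [
    "CorrespondenceGraph",
    "SimilarityResult",
    "RigidTransform",
    "TooLargeComparisonError",
    "distance_compatible",
    "build_correspondence_graph",
    "maximal_cliques",
    "superimpose",
    "count_overlaps",
    "similarity_index",
    "compare",
    "search_reference",
    "DISTANCE_RATIO",
    "OVERLAP_THRESHOLD",
    "MIN_OVERLAPPED_PAIRS",
    "MIN_SI",
    "CLIQUE_VERTEX_CAP",
]

DISTANCE_RATIO = 1.1
OVERLAP_THRESHOLD = 1.0  # Angstrom
MIN_OVERLAPPED_PAIRS = 5
MIN_SI = 0.10
CLIQUE_VERTEX_CAP = 2000


class TooLargeComparisonError(RuntimeError):
    """Correspondence graph exceeds the configured vertex cap."""


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class CorrespondenceGraph:
    """Vertices are matched (p, q) node-index pairs; edges mark
    distance-compatible vertex pairs."""

    graph: nx.Graph
    p_nodes: list[FingerprintNode]
    q_nodes: list[FingerprintNode]


@dataclass
class SimilarityResult:
    n_p: int
    n_q: int
    n_pq: int
    si: float
    mapping: list[tuple[FingerprintNode, FingerprintNode]] = field(
        default_factory=list)
    transform: Optional[RigidTransform] = None  # maps Q coords onto P
    qualified: bool = False


def distance_compatible(d1: float, d2: float, k: float = DISTANCE_RATIO) -> bool:
    """True iff the larger distance is under k times the smaller
    (equal distances, including zero, are compatible by convention)."""
    if d1 == d2:
        return True
    lo, hi = (d1, d2) if d1 < d2 else (d2, d1)
    return hi < k * lo


def build_correspondence_graph(
    P: Fingerprint,
    Q: Fingerprint,
    k: float = DISTANCE_RATIO,
    mode: Optional[str] = None,
) -> CorrespondenceGraph:
    """Correspondence graph between two fingerprints.

    A vertex (i, j) exists for every same-kind, same-label pair of nodes
    (P.nodes[i], Q.nodes[j]). Vertices (i1, j1), (i2, j2) with i1 != i2
    and j1 != j2 are joined iff dist(p_i1, p_i2) is compatible with
    dist(q_j1, q_j2). ``mode`` = "protein_only" restricts both node sets
    to protein nodes.
    """
    p_nodes = P.nodes_for_mode(mode)
    q_nodes = Q.nodes_for_mode(mode)
    g = nx.Graph()
    vertices = [
        (i, j)
        for i, p in enumerate(p_nodes)
        for j, q in enumerate(q_nodes)
        if p.kind == q.kind and p.label == q.label
    ]
    g.add_nodes_from(vertices)
    p_xyz = np.array([n.coords for n in p_nodes]) if p_nodes else np.empty((0, 3))
    q_xyz = np.array([n.coords for n in q_nodes]) if q_nodes else np.empty((0, 3))
    for a in range(len(vertices)):
        i1, j1 = vertices[a]
        for b in range(a + 1, len(vertices)):
            i2, j2 = vertices[b]
            if i1 == i2 or j1 == j2:
                continue
            d1 = float(np.linalg.norm(p_xyz[i1] - p_xyz[i2]))
            d2 = float(np.linalg.norm(q_xyz[j1] - q_xyz[j2]))
            if distance_compatible(d1, d2, k):
                g.add_edge(vertices[a], vertices[b])
    return CorrespondenceGraph(graph=g, p_nodes=p_nodes, q_nodes=q_nodes)


def maximal_cliques(
    graph: nx.Graph | CorrespondenceGraph,
    cap: int = CLIQUE_VERTEX_CAP,
) -> list[list]:
    """All maximum-cardinality cliques, in deterministic order.

    Uses Bron-Kerbosch with pivoting. Graphs over ``cap`` vertices abort
    with :class:`TooLargeComparisonError` rather than risk a runaway
    enumeration.
    """
    g = graph.graph if isinstance(graph, CorrespondenceGraph) else graph
    if g.number_of_nodes() > cap:
        raise TooLargeComparisonError(
            f"correspondence graph has {g.number_of_nodes()} vertices "
            f"(cap {cap})")
    if g.number_of_nodes() == 0:
        return []
    best = 0
    cliques = []
    for clique in nx.find_cliques(g):
        if len(clique) > best:
            best = len(clique)
            cliques = [clique]
        elif len(clique) == best:
            cliques.append(clique)
    cliques = [sorted(c) for c in cliques]
    cliques.sort()
    return cliques


def superimpose(
    pairs_p: np.ndarray, pairs_q: np.ndarray
) -> RigidTransform:
    """Least-squares rigid transform mapping the Q points onto the P
    points (Kabsch; reflections are never produced).

    With fewer than three pairs (or effectively collinear point sets)
    the rotation is under-determined; a translation-only transform
    aligning centroids is returned.
    """
    pairs_p = np.asarray(pairs_p, float).reshape(-1, 3)
    pairs_q = np.asarray(pairs_q, float).reshape(-1, 3)
    cp = pairs_p.mean(axis=0)
    cq = pairs_q.mean(axis=0)
    if len(pairs_p) < 3:
        return RigidTransform(np.eye(3), cp - cq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-set chatter from scipy
        rot, _ = Rotation.align_vectors(pairs_p - cp, pairs_q - cq)
    R = rot.as_matrix()
    return RigidTransform(R, cp - R @ cq)


def count_overlaps(
    transform: RigidTransform,
    vertices: Sequence[tuple[int, int]],
    p_nodes: Sequence[FingerprintNode],
    q_nodes: Sequence[FingerprintNode],
    threshold: float = OVERLAP_THRESHOLD,
) -> tuple[int, list[tuple[int, int]]]:
    """Count geometrically overlapped matched pairs after superposition.

    All matched vertices are considered, not only clique members. A pair
    overlaps iff its post-transform distance is strictly below
    ``threshold``; each node is used at most once, conflicts resolved by
    greedy nearest-first assignment (ties broken by vertex order).
    """
    candidates = []
    for idx, (i, j) in enumerate(vertices):
        d = float(np.linalg.norm(
            p_nodes[i].xyz - transform.apply(q_nodes[j].xyz)))
        if d < threshold:
            candidates.append((d, idx, i, j))
    candidates.sort(key=lambda t: (t[0], t[1]))
    used_p: set[int] = set()
    used_q: set[int] = set()
    mapping: list[tuple[int, int]] = []
    for _, _, i, j in candidates:
        if i in used_p or j in used_q:
            continue
        used_p.add(i)
        used_q.add(j)
        mapping.append((i, j))
    return len(mapping), mapping


def similarity_index(n_p: int, n_q: int, n_pq: int) -> float:
    """Tanimoto index SI = Npq / (Np + Nq - Npq); 0 for two empty sets."""
    if n_pq > min(n_p, n_q):
        raise ValueError("overlap count exceeds fingerprint size")
    denom = n_p + n_q - n_pq
    if denom == 0:
        return 0.0
    return n_pq / denom


def compare(
    P: Fingerprint,
    Q: Fingerprint,
    k: float = DISTANCE_RATIO,
    overlap_threshold: float = OVERLAP_THRESHOLD,
    min_overlapped: int = MIN_OVERLAPPED_PAIRS,
    mode: Optional[str] = None,
    clique_cap: int = CLIQUE_VERTEX_CAP,
) -> SimilarityResult:
    """Full similarity computation between two fingerprints.

    Every maximum clique seeds a superposition; among all solutions the
    one with the most overlapped pairs wins (ties fall to the first
    clique in deterministic order). Comparison runs in a canonical
    direction (the lexicographically smaller complex_id is the target)
    so that compare(P, Q) and compare(Q, P) agree exactly.
    """
    swapped = Q.complex_id < P.complex_id
    A, B = (Q, P) if swapped else (P, Q)

    corr = build_correspondence_graph(A, B, k=k, mode=mode)
    n_a, n_b = len(corr.p_nodes), len(corr.q_nodes)
    vertices = list(corr.graph.nodes)
    best_n = 0
    best_mapping: list[tuple[int, int]] = []
    best_transform: Optional[RigidTransform] = None
    for clique in maximal_cliques(corr, cap=clique_cap):
        pp = np.array([corr.p_nodes[i].coords for i, _ in clique])
        qq = np.array([corr.q_nodes[j].coords for _, j in clique])
        transform = superimpose(pp, qq)
        n_pq, mapping = count_overlaps(
            transform, vertices, corr.p_nodes, corr.q_nodes,
            threshold=overlap_threshold)
        if n_pq > best_n:
            best_n, best_mapping, best_transform = n_pq, mapping, transform

    si = similarity_index(n_a, n_b, best_n)
    mapping_nodes = [(corr.p_nodes[i], corr.q_nodes[j])
                     for i, j in best_mapping]
    if swapped:
        mapping_nodes = [(q, p) for p, q in mapping_nodes]
        if best_transform is not None:
            best_transform = best_transform.inverse()
        n_a, n_b = n_b, n_a
    return SimilarityResult(
        n_p=n_a, n_q=n_b, n_pq=best_n, si=si,
        mapping=mapping_nodes, transform=best_transform,
        qualified=best_n >= min_overlapped)


def search_reference(
    query: Fingerprint,
    library: Iterable[Fingerprint],
    min_si: float = MIN_SI,
    exclude_ids: Iterable[str] = (),
    mode: Optional[str] = None,
    k: float = DISTANCE_RATIO,
    return_all: bool = False,
):
    """Best qualified reference for a query fingerprint.

    Candidates must be qualified (>= 5 overlapped pairs) with SI at
    least ``min_si``; the query's own complex_id and any id in
    ``exclude_ids`` are never considered. Ties resolve by highest SI,
    then largest overlap count, then lexicographically smallest
    complex_id. Returns ``(fingerprint, result)`` or ``(None, None)``;
    with ``return_all`` a ranked list of (fingerprint, result) for every
    candidate compared.
    """
    excluded = set(exclude_ids) | {query.complex_id}
    ranked: list[tuple[Fingerprint, SimilarityResult]] = []
    library = list(library)
    if not library:
        warnings.warn("empty reference library")
    for candidate in library:
        if candidate.complex_id in excluded:
            continue
        result = compare(query, candidate, k=k, mode=mode)
        ranked.append((candidate, result))
    ranked.sort(key=lambda t: (-t[1].si, -t[1].n_pq, t[0].complex_id))
    if return_all:
        return ranked
    for candidate, result in ranked:
        if result.qualified and result.si >= min_si:
            return candidate, result
    return None, None
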