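"""Relational graphs and the proximity metrics defined on them.

A :class:`RelationalGraph` is the latent structure that generates stimulus
sequences: nodes are objects, undirected edges are the transitions a learner
can experience directly.  Everything downstream — adaptation analyses,
response-time regressions, map recovery — is parametric in one of the
pairwise proximity metrics computed here:

* link distance (minimum number of edges between two nodes),
* Euclidean distance in a planar layout with unit-length links,
* communicability, the negative matrix exponential ``-exp(A)`` of the
  adjacency matrix (a factorially discounted sum over walks of all lengths),
* the successor representation ``(I - γA)⁻¹`` (discounted expected future
  occupancy; the matrix resolvent),
* weighted shortest paths over empirically experienced transition counts.

The module also provides the permutation-null machinery: exhaustive
enumeration of all connected graphs with a fixed edge count on a labelled
node set, and a planar line-crossing counter.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.linalg

__all__ = [
    "RelationalGraph",
    "TransitionCountMatrix",
    "ProximityMatrix",
    "NullGraphEnsemble",
    "default_reduced_graph",
    "default_training_graph",
    "link_distance_matrix",
    "euclidean_distance_matrix",
    "communicability_matrix",
    "successor_representation_matrix",
    "negative_successor_matrix",
    "proximity_matrix",
    "asymmetry_index",
    "empirical_edge_lengths",
    "directed_shortest_paths",
    "enumerate_null_graphs",
    "count_line_crossings",
    "segments_cross",
    "ensemble_link_correlations",
    "ensemble_crossing_counts",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationalGraph:
    """An undirected, connected relational graph with an optional 2-D layout.

    Parameters
    ----------
    node_labels : sequence
        Ordered node identifiers; the order fixes matrix indexing everywhere.
    edges : iterable of pairs
        Unordered node pairs. Self-loops and duplicates are rejected.
    layout : mapping, optional
        Node -> (x, y) planar coordinates in arbitrary units.  When present
        it must cover every node.
    """

    node_labels: tuple
    edges: frozenset
    layout: dict | None = field(default=None, compare=False)

    def __init__(self, node_labels, edges, layout=None):
        labels = tuple(node_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels")
        label_set = set(labels)
        canon = set()
        for e in edges:
            a, b = e
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in label_set or b not in label_set:
                raise ValueError(f"edge {(a, b)!r} references unknown node")
            key = frozenset((a, b))
            if key in canon:
                raise ValueError(f"duplicate edge {(a, b)!r}")
            canon.add(key)
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from(tuple(e) for e in canon)
        if len(labels) and not nx.is_connected(g):
            comp = min(nx.connected_components(g), key=len)
            raise ValueError(
                f"graph is disconnected: nodes {sorted(comp, key=str)} are "
                "unreachable from the rest"
            )
        if layout is not None:
            layout = {k: (float(v[0]), float(v[1])) for k, v in layout.items()}
            missing = label_set - set(layout)
            if missing:
                raise ValueError(f"layout missing nodes {sorted(missing, key=str)}")
        object.__setattr__(self, "node_labels", labels)
        object.__setattr__(self, "edges", frozenset(canon))
        object.__setattr__(self, "layout", layout)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node) -> int:
        return self.node_labels.index(node)

    def adjacency(self) -> np.ndarray:
        """Binary symmetric adjacency matrix in node-label order."""
        n = self.n_nodes
        idx = {v: i for i, v in enumerate(self.node_labels)}
        a = np.zeros((n, n))
        for e in self.edges:
            i, j = (idx[v] for v in e)
            a[i, j] = a[j, i] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def neighbors(self, node) -> list:
        return sorted((set(e) - {node}).pop() for e in self.edges if node in e)

    def has_edge(self, a, b) -> bool:
        return frozenset((a, b)) in self.edges

    def edge_list(self) -> list[tuple]:
        """Edges as sorted tuples, in deterministic order."""
        return sorted((tuple(sorted(e, key=str)) for e in self.edges), key=str)


@dataclass(frozen=True)
class TransitionCountMatrix:
    """Directed counts of experienced transitions: entry (i, j) is the number
    of trials on which object j was immediately preceded by object i."""

    counts: np.ndarray
    node_labels: tuple

    def __init__(self, counts, node_labels):
        counts = np.asarray(counts)
        labels = tuple(node_labels)
        if counts.shape != (len(labels), len(labels)):
            raise ValueError("count matrix shape does not match node labels")
        if np.any(counts < 0):
            raise ValueError("negative transition count")
        if np.any(np.diag(counts) != 0):
            raise ValueError("diagonal counts must be zero (objects never repeat)")
        object.__setattr__(self, "counts", counts.astype(int))
        object.__setattr__(self, "node_labels", labels)

    def count(self, i, j) -> int:
        return int(self.counts[self.node_labels.index(i), self.node_labels.index(j)])

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ProximityMatrix:
    """A pairwise proximity/distance metric over the nodes of a graph."""

    values: np.ndarray
    metric_kind: str
    node_labels: tuple
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    def value(self, i, j) -> float:
        return float(self.values[self.node_labels.index(i), self.node_labels.index(j)])

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle values as a flat vector."""
        iu = np.triu_indices(len(self.node_labels), k=1)
        return self.values[iu]


@dataclass(frozen=True)
class NullGraphEnsemble:
    """Exhaustive ensemble of connected graphs on a fixed labelled node set
    with a fixed number of edges; the permutation null for map recovery."""

    node_labels: tuple
    members: tuple  # tuple of frozenset-of-frozenset edge sets

    def __len__(self) -> int:
        return len(self.members)

    def edge_index_masks(self) -> tuple[np.ndarray, list[tuple]]:
        """Boolean membership matrix (n_members, n_possible_edges) plus the
        canonical list of possible edges, for vectorised ensemble statistics."""
        possible = list(itertools.combinations(self.node_labels, 2))
        pos = {frozenset(e): k for k, e in enumerate(possible)}
        masks = np.zeros((len(self.members), len(possible)), dtype=bool)
        for m, edges in enumerate(self.members):
            for e in edges:
                masks[m, pos[e]] = True
        return masks, possible


# ---------------------------------------------------------------------------
# Default graphs
# ---------------------------------------------------------------------------

_PENTAGON_ORDER = (1, 4, 6, 3, 5)  # cycle order of the inner 5-cycle
_REDUCED_EDGES = ((1, 2), (1, 4), (1, 5), (3, 5), (3, 6), (4, 6), (5, 7))
_PENDANTS = {2: 1, 7: 5}  # pendant -> anchor on the pentagon


def _pentagon_layout() -> dict:
    """Exact unit-edge planar layout: regular pentagon (side 1) for the
    5-cycle, pendants extended radially at unit distance."""
    r = 1.0 / (2.0 * math.sin(math.pi / 5.0))
    ang = {v: math.radians(90.0 - 72.0 * k) for k, v in enumerate(_PENTAGON_ORDER)}
    layout = {v: (r * math.cos(a), r * math.sin(a)) for v, a in ang.items()}
    for pend, anchor in _PENDANTS.items():
        a = ang[anchor]
        layout[pend] = ((r + 1.0) * math.cos(a), (r + 1.0) * math.sin(a))
    return layout


def default_reduced_graph() -> RelationalGraph:
    """The default 7-node, 7-edge reduced graph used on the test day.

    A 5-cycle 1–4–6–3–5 with pendant nodes 2 (attached to 1) and 7 (attached
    to 5); diameter 3; shipped with an exact unit-edge planar layout.
    """
    return RelationalGraph(range(1, 8), _REDUCED_EDGES, layout=_pentagon_layout())


def default_training_graph() -> RelationalGraph:
    """The default 12-node training graph.

    Contains the reduced graph as an induced subgraph on nodes 1–7, plus an
    outer ring 8–9–10–11–12 with spokes to nodes 2, 4, 6, 3 and 7, giving
    every node degree >= 2 so the window-constrained random walk never gets
    stuck irrecoverably.
    """
    ring = [(8, 9), (9, 10), (10, 11), (11, 12), (12, 8)]
    spokes = [(8, 2), (9, 4), (10, 6), (11, 3), (12, 7)]
    edges = list(_REDUCED_EDGES) + ring + spokes
    inner = _pentagon_layout()
    r = 1.0 / (2.0 * math.sin(math.pi / 5.0))
    spoke_anchor = {8: 2, 9: 4, 10: 6, 11: 3, 12: 7}
    layout = dict(inner)
    for outer, anchor in spoke_anchor.items():
        x, y = inner[anchor]
        a = math.atan2(y, x)
        layout[outer] = ((r + 2.0) * math.cos(a), (r + 2.0) * math.sin(a))
    return RelationalGraph(range(1, 13), edges, layout=layout)


# ---------------------------------------------------------------------------
# Proximity metrics
# ---------------------------------------------------------------------------


def link_distance_matrix(graph: RelationalGraph) -> ProximityMatrix:
    """Minimum number of edges between every node pair (link distance)."""
    g = graph.to_networkx()
    n = graph.n_nodes
    d = np.zeros((n, n))
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for i, u in enumerate(graph.node_labels):
        for j, v in enumerate(graph.node_labels):
            try:
                d[i, j] = lengths[u][v]
            except KeyError:
                raise ValueError(f"nodes {u!r} and {v!r} are not connected") from None
    return ProximityMatrix(d, "link", graph.node_labels)


def euclidean_distance_matrix(graph: RelationalGraph) -> ProximityMatrix:
    """Straight-line distance between layout coordinates of every node pair."""
    if graph.layout is None:
        raise ValueError("graph has no layout; Euclidean distances undefined")
    pts = np.array([graph.layout[v] for v in graph.node_labels])
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return ProximityMatrix(d, "euclidean", graph.node_labels)


def communicability_matrix(graph: RelationalGraph) -> ProximityMatrix:
    """Communicability: the negative matrix exponential ``-exp(A)``.

    The matrix exponential sums walks of every length with factorial
    discounting, so it is large for nearby nodes; its negative scales like a
    distance and is used directly as the regressor.
    """
    a = graph.adjacency()
    return ProximityMatrix(-scipy.linalg.expm(a), "communicability", graph.node_labels)


def successor_representation_matrix(
    graph: RelationalGraph, gamma_fraction: float
) -> ProximityMatrix:
    """Successor representation ``(I - γA)⁻¹`` with ``γ = gamma_fraction/λmax``.

    ``λmax`` is the spectral radius of the adjacency matrix; the geometric
    series converges only for ``γ·λmax < 1``, hence ``gamma_fraction`` must
    lie in [0, 1).  ``gamma_fraction = 0`` gives the identity.
    """
    if gamma_fraction >= 1.0:
        raise ValueError(
            f"gamma_fraction={gamma_fraction} >= 1: the discounted walk series "
            "does not converge (requires gamma * lambda_max < 1)"
        )
    if gamma_fraction < 0.0:
        raise ValueError("gamma_fraction must be non-negative")
    a = graph.adjacency()
    lam = float(np.max(np.abs(np.linalg.eigvals(a)))) if graph.n_edges else 1.0
    gamma = gamma_fraction / lam if lam > 0 else 0.0
    n = graph.n_nodes
    sr = np.linalg.inv(np.eye(n) - gamma * a)
    return ProximityMatrix(
        sr,
        "successor",
        graph.node_labels,
        params={"gamma_fraction": gamma_fraction, "gamma": gamma, "lambda_max": lam},
    )


def negative_successor_matrix(
    graph: RelationalGraph, gamma_fraction: float
) -> ProximityMatrix:
    """Negative successor representation — the distance-like regressor form."""
    sr = successor_representation_matrix(graph, gamma_fraction)
    return ProximityMatrix(-sr.values, "successor", graph.node_labels, params=sr.params)


def proximity_matrix(
    graph: RelationalGraph, kind: str, gamma_fraction: float = 0.85
) -> ProximityMatrix:
    """Distance-like proximity matrix of the requested kind.

    All kinds scale *positively* with distance on the graph (communicability
    and the successor representation are negated), so a positive regression
    coefficient always means "response grows with distance".
    """
    if kind == "link":
        return link_distance_matrix(graph)
    if kind == "euclidean":
        return euclidean_distance_matrix(graph)
    if kind == "communicability":
        return communicability_matrix(graph)
    if kind == "successor":
        return negative_successor_matrix(graph, gamma_fraction)
    raise ValueError(f"unknown proximity metric kind: {kind!r}")


# ---------------------------------------------------------------------------
# Experience-derived measures
# ---------------------------------------------------------------------------


def asymmetry_index(counts: TransitionCountMatrix, i, j) -> float:
    """Directional imbalance a = |c_ij − c_ji| / (c_ij + c_ji) in [0, 1].

    0 means the transition was experienced equally often in both directions;
    1 means it was only ever experienced one way.
    """
    xy = counts.count(i, j)
    yx = counts.count(j, i)
    if xy + yx == 0:
        raise ValueError(f"transition {i!r}<->{j!r} never experienced in either direction")
    return abs(xy - yx) / (xy + yx)


def empirical_edge_lengths(
    counts: TransitionCountMatrix, graph: RelationalGraph
) -> dict[tuple, float]:
    """Directed edge weights d = 1 − c/(1 + cmax) from experienced counts.

    ``cmax`` is the maximum directed count over the graph's edges.  Often-
    travelled transitions become short (d near 1/(1+cmax) at c = cmax);
    never-travelled edges keep length 1.  Returns one weight per directed
    edge of the graph.
    """
    if counts.node_labels != graph.node_labels:
        raise ValueError("count matrix and graph use different node labels")
    directed = [(a, b) for e in graph.edges for a, b in (tuple(e), tuple(e)[::-1])]
    cmax = max(counts.count(a, b) for a, b in directed)
    if cmax <= 0:
        raise ValueError("no graph edge was ever experienced; cmax must be > 0")
    return {
        (a, b): 1.0 - counts.count(a, b) / (1.0 + cmax) for (a, b) in directed
    }


def directed_shortest_paths(
    edge_weights: Mapping[tuple, float],
    graph: RelationalGraph,
    symmetrised: bool = False,
) -> ProximityMatrix:
    """Shortest weighted path between every ordered node pair.

    Entry (i, j) is the minimum total weight over directed paths i -> j using
    the supplied per-direction edge weights.  With ``symmetrised=True`` the
    two directions are averaged, giving the non-directional variant.
    """
    for (a, b), w in edge_weights.items():
        if w <= 0:
            raise ValueError(f"non-positive weight {w} on edge {(a, b)!r}")
    dg = nx.DiGraph()
    dg.add_nodes_from(graph.node_labels)
    for (a, b), w in edge_weights.items():
        dg.add_edge(a, b, weight=w)
    n = graph.n_nodes
    d = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(dg, weight="weight"))
    for i, u in enumerate(graph.node_labels):
        for j, v in enumerate(graph.node_labels):
            if i == j:
                continue
            try:
                d[i, j] = lengths[u][v]
            except KeyError:
                raise ValueError(f"node {v!r} unreachable from {u!r}") from None
    kind = "weighted_shortest_path"
    if symmetrised:
        d = 0.5 * (d + d.T)
        return ProximityMatrix(d, kind, graph.node_labels, params={"symmetrised": True})
    return ProximityMatrix(d, kind, graph.node_labels, params={"symmetrised": False})


# ---------------------------------------------------------------------------
# Permutation null: exhaustive connected-graph enumeration
# ---------------------------------------------------------------------------


def _connected_edge_mask(n_nodes: int, edges: Sequence[tuple[int, int]]) -> bool:
    """Union-find connectivity over integer-indexed nodes."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = n_nodes
    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            comps -= 1
    return comps == 1


def enumerate_null_graphs(
    n_nodes: int, n_edges: int, node_labels: Sequence | None = None
) -> NullGraphEnsemble:
    """All connected simple graphs on a labelled node set with exactly
    ``n_edges`` edges.

    Enumerates every ``n_edges``-element subset of the C(n, 2) possible
    edges and keeps the connected ones (union-find filter).  For 7 nodes and
    7 edges this scans 116,280 candidate edge sets and retains 68,295.
    """
    if node_labels is None:
        node_labels = tuple(range(1, n_nodes + 1))
    node_labels = tuple(node_labels)
    if len(node_labels) != n_nodes:
        raise ValueError("node_labels length must equal n_nodes")
    if n_edges < n_nodes - 1:
        raise ValueError(
            f"{n_edges} edges cannot connect {n_nodes} nodes (need >= {n_nodes - 1})"
        )
    possible = list(itertools.combinations(range(n_nodes), 2))
    if n_edges > len(possible):
        raise ValueError("more edges requested than exist on the node set")
    members = []
    for subset in itertools.combinations(possible, n_edges):
        if _connected_edge_mask(n_nodes, subset):
            members.append(
                frozenset(frozenset((node_labels[a], node_labels[b])) for a, b in subset)
            )
    return NullGraphEnsemble(node_labels=node_labels, members=tuple(members))


# ---------------------------------------------------------------------------
# Planar line crossings
# ---------------------------------------------------------------------------


def _orient(p, q, r) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def segments_cross(p1, p2, p3, p4) -> bool:
    """True when open segments (p1,p2) and (p3,p4) properly intersect.

    Segments sharing an endpoint never cross; an endpoint merely touching the
    other segment's interior does not count; collinear segments overlapping
    in more than a point do count.
    """
    pts = {tuple(p1), tuple(p2)} & {tuple(p3), tuple(p4)}
    if pts:
        return False
    d1 = _orient(p3, p4, p1)
    d2 = _orient(p3, p4, p2)
    d3 = _orient(p1, p2, p3)
    d4 = _orient(p1, p2, p4)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != 0 and d2 != 0 and d3 != 0 and d4 != 0:
        return True
    if d1 == 0 and d2 == 0 and d3 == 0 and d4 == 0:
        # collinear: crossing iff the 1-D projections overlap in more than a point
        axis = 0 if abs(p2[0] - p1[0]) >= abs(p2[1] - p1[1]) else 1
        a0, a1 = sorted((p1[axis], p2[axis]))
        b0, b1 = sorted((p3[axis], p4[axis]))
        return min(a1, b1) - max(a0, b0) > 0
    return False


def count_line_crossings(layout: Mapping, edges: Iterable[tuple]) -> int:
    """Number of unordered edge pairs whose segments properly cross in the
    given layout.  A faithful 2-D map has zero crossings."""
    seg = [(layout[a], layout[b]) for a, b in (tuple(e) for e in edges)]
    labels = [tuple(e) for e in edges]
    count = 0
    for (s1, l1), (s2, l2) in itertools.combinations(zip(seg, labels), 2):
        if set(l1) & set(l2):
            continue
        if segments_cross(s1[0], s1[1], s2[0], s2[1]):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Vectorised ensemble statistics
# ---------------------------------------------------------------------------


def _batched_link_distances(
    masks: np.ndarray, possible: list[tuple], node_labels: tuple
) -> np.ndarray:
    """Link-distance matrices for every ensemble member at once.

    masks is (G, E) edge membership over the canonical possible-edge list;
    returns (G, n, n) float distances in node-label order (members are
    connected, so all entries are finite).
    """
    g = masks.shape[0]
    n = len(node_labels)
    adj = np.zeros((g, n, n), dtype=np.uint8)
    idx = {lab: k for k, lab in enumerate(node_labels)}
    for e_k, (a, b) in enumerate(possible):
        ia, ib = idx[a], idx[b]
        sel = masks[:, e_k]
        adj[sel, ia, ib] = 1
        adj[sel, ib, ia] = 1
    dist = np.full((g, n, n), np.inf)
    eye = np.eye(n, dtype=bool)
    dist[:, eye] = 0.0
    reach = adj.astype(np.int32)
    for k in range(1, n):
        newly = (reach > 0) & np.isinf(dist)
        dist[newly] = k
        if not np.isinf(dist).any():
            break
        reach = np.matmul(reach, adj.astype(np.int32))
        np.clip(reach, 0, 1, out=reach)
    return dist


def ensemble_link_correlations(
    ensemble: NullGraphEnsemble, target_distances: np.ndarray
) -> np.ndarray:
    """Pearson correlation of each member's link distances with a target
    pairwise-distance vector (off-diagonal upper triangle, node-label order)."""
    masks, possible = ensemble.edge_index_masks()
    n = len(ensemble.node_labels)
    dist = _batched_link_distances(masks, possible, ensemble.node_labels)
    iu = np.triu_indices(n, k=1)
    x = dist[:, iu[0], iu[1]]  # (G, n_pairs)
    y = np.asarray(target_distances, dtype=float)
    if y.shape != (x.shape[1],):
        raise ValueError("target distance vector has wrong length")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore"):
        r = (xc @ yc) / denom
    return np.nan_to_num(r, nan=0.0)


def ensemble_crossing_counts(
    ensemble: NullGraphEnsemble, layout: Mapping
) -> np.ndarray:
    """Line-crossing count of every ensemble member at a fixed node layout."""
    masks, possible = ensemble.edge_index_masks()
    ne = len(possible)
    cross = np.zeros((ne, ne), dtype=bool)
    for a_k, b_k in itertools.combinations(range(ne), 2):
        ea, eb = possible[a_k], possible[b_k]
        if set(ea) & set(eb):
            continue
        if segments_cross(layout[ea[0]], layout[ea[1]], layout[eb[0]], layout[eb[1]]):
            cross[a_k, b_k] = True
    m = masks.astype(np.int64)
    return np.einsum("gi,ij,gj->g", m, cross.astype(np.int64), m)
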