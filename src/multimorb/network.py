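"""Weighted disease co-occurrence networks and Louvain community detection.

Nodes are chronic conditions (filtered at a minimum marginal prevalence);
an undirected edge joins two conditions with weight equal to their joint
prevalence — the fraction of participants carrying both conditions among
those with both states observed (pairwise-available denominators) — or,
alternatively, the Jaccard index of the two participant sets.

Community detection is an in-repo implementation of the Louvain two-phase
heuristic (greedy local moving followed by graph aggregation) maximizing
Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j)

with weighted degrees k and total edge weight m.  networkx is used only
for interchange (GraphML export); metrics, modularity and Louvain itself
are computed here so they can be validated against independent
graph-library oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import CONDITIONS

__all__ = [
    "CoOccurrenceNetwork",
    "CommunityPartition",
    "NetworkMetrics",
    "EmptyNetworkError",
    "LouvainCommunities",
    "build_network",
    "network_metrics",
    "modularity",
    "louvain",
    "best_partition_exhaustive",
    "sensitivity_sweep",
]

DEFAULT_LOUVAIN_SEED = 20240701


class EmptyNetworkError(ValueError):
    """No nodes survive the prevalence filter."""


class UndefinedModularityError(ZeroDivisionError):
    """Modularity requested on a graph with zero total edge weight."""


@dataclass
class CoOccurrenceNetwork:
    """Undirected weighted condition network.

    Edges are canonical ``(i, j, weight)`` with ``i < j`` in node order,
    no self-loops, and ``weight > edge_threshold``.  Weights are fractions
    internally; reports format them as percentages.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    weight_scheme: str = "joint_prevalence"
    min_node_prevalence: float = 0.05
    edge_threshold: float = 0.0
    node_prevalence: dict[str, float] = field(default_factory=dict)

    def adjacency(self) -> np.ndarray:
        """Dense weighted adjacency in node order."""
        idx = {v: k for k, v in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes), len(self.nodes)))
        for i, j, w in self.edges:
            A[idx[i], idx[j]] = A[idx[j], idx[i]] = w
        return A

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        G.add_weighted_edges_from(self.edges)
        return G

    def edge_frame(self, as_percent: bool = True) -> pd.DataFrame:
        w = [(100.0 * e[2] if as_percent else e[2]) for e in self.edges]
        return pd.DataFrame(
            {
                "node_i": [e[0] for e in self.edges],
                "node_j": [e[1] for e in self.edges],
                "weight": w,
            }
        )


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity score."""

    assignment: dict[str, int]
    modularity: float
    resolution: float = 1.0
    seed: int = DEFAULT_LOUVAIN_SEED

    def __post_init__(self) -> None:
        if not -1.0 <= self.modularity <= 1.0:
            raise ValueError("modularity outside [-1, 1]")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[frozenset]:
        out: dict[int, set] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [frozenset(s) for s in out.values()]


@dataclass(frozen=True)
class NetworkMetrics:
    """Size, density, transitivity and hop diameter of the unweighted skeleton."""

    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float
    diameter: int
    connected: bool = True


def build_network(
    panel: pd.DataFrame,
    weight_scheme: str = "joint_prevalence",
    min_node_prevalence: float = 0.05,
    edge_threshold: float = 0.0,
    conditions: Sequence[str] | None = None,
) -> CoOccurrenceNetwork:
    """Build the condition co-occurrence network from a ternary panel table.

    Node marginal prevalence uses each condition's own available
    denominator; edge weights use pairwise-available denominators.  Edges
    with weight <= ``edge_threshold`` (and pairs never jointly observed)
    are dropped.
    """
    if len(panel) == 0:
        raise EmptyNetworkError("empty panel table")
    if weight_scheme not in ("joint_prevalence", "jaccard"):
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    conds = list(conditions) if conditions is not None else [c for c in CONDITIONS if c in panel]
    M = panel[conds].to_numpy(dtype=float)
    observed = ~np.isnan(M)
    present = np.where(observed, M == 1.0, False).astype(float)
    obs = observed.astype(float)

    denom = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(denom > 0, present.sum(axis=0) / denom, 0.0)
    keep = prev >= min_node_prevalence
    nodes = [c for c, k in zip(conds, keep) if k]
    if not nodes:
        raise EmptyNetworkError("no conditions at or above the prevalence filter")
    P, O = present[:, keep], obs[:, keep]
    prev = prev[keep]

    n11 = P.T @ P  # both present (necessarily both observed)
    n_obs = O.T @ O  # both observed
    union = P.T @ O + O.T @ P - n11  # at least one present among both-observed

    edges = []
    for a, b in itertools.combinations(range(len(nodes)), 2):
        if n_obs[a, b] == 0:
            continue
        if weight_scheme == "joint_prevalence":
            w = n11[a, b] / n_obs[a, b]
        else:
            w = n11[a, b] / union[a, b] if union[a, b] > 0 else 0.0
        if w > edge_threshold:
            edges.append((nodes[a], nodes[b], float(w)))
    return CoOccurrenceNetwork(
        nodes=tuple(nodes),
        edges=tuple(edges),
        weight_scheme=weight_scheme,
        min_node_prevalence=min_node_prevalence,
        edge_threshold=edge_threshold,
        node_prevalence={c: float(p) for c, p in zip(nodes, prev)},
    )


# -- metrics on the unweighted skeleton ---------------------------------


def _skeleton(net: CoOccurrenceNetwork) -> np.ndarray:
    A = net.adjacency()
    return (A > 0).astype(int)


def _bfs_ecc(A01: np.ndarray, source: int) -> tuple[np.ndarray, int]:
    n = len(A01)
    dist = np.full(n, -1)
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(A01[u]):
                if dist[v] < 0:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist, int(dist.max(initial=0))


def network_metrics(net: CoOccurrenceNetwork) -> NetworkMetrics:
    """Density, global transitivity and hop diameter of the network skeleton.

    A disconnected network reports the diameter of its largest component
    with ``connected=False``.
    """
    A = _skeleton(net)
    n = len(A)
    if n == 0:
        raise EmptyNetworkError("metrics on an empty network")
    e = int(A.sum() // 2)
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    deg = A.sum(axis=1)
    triples = float(np.sum(deg * (deg - 1) / 2))
    triangles = float(np.trace(A @ A @ A)) / 6.0
    transitivity = 3.0 * triangles / triples if triples > 0 else 0.0

    dists = [_bfs_ecc(A, s)[0] for s in range(n)]
    connected = all((d >= 0).all() for d in dists)
    if connected:
        diameter = max(int(d.max()) for d in dists) if n > 1 else 0
    else:
        # largest component via repeated BFS
        unseen = set(range(n))
        best_comp: list[int] = []
        while unseen:
            s = next(iter(unseen))
            comp = [v for v in range(n) if dists[s][v] >= 0]
            if len(comp) > len(best_comp):
                best_comp = comp
            unseen -= set(comp)
        sub = A[np.ix_(best_comp, best_comp)]
        diameter = max(_bfs_ecc(sub, s)[1] for s in range(len(best_comp))) if len(best_comp) > 1 else 0
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        density=density,
        clustering_coefficient=transitivity,
        diameter=diameter,
        connected=connected,
    )


# -- modularity and Louvain ---------------------------------------------


def _as_adjacency(net) -> tuple[np.ndarray, list]:
    """Accept a CoOccurrenceNetwork, a dense adjacency, or a networkx graph."""
    if isinstance(net, CoOccurrenceNetwork):
        return net.adjacency(), list(net.nodes)
    if isinstance(net, np.ndarray):
        A = np.asarray(net, dtype=float)
        return A, list(range(len(A)))
    try:
        import networkx as nx

        if isinstance(net, nx.Graph):
            nodes = list(net.nodes)
            A = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
            return A, nodes
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"cannot interpret {type(net)!r} as a weighted graph")


def modularity(net, assignment: Mapping, resolution: float = 1.0) -> float:
    """Weighted Newman-Girvan modularity of a node -> community assignment.

    Self-loop weights count once in A_ii and twice in the degree, matching
    the standard convention of graph libraries.
    """
    A, nodes = _as_adjacency(net)
    comm = np.asarray([assignment[v] for v in nodes])
    k = A.sum(axis=1) + np.diag(A)  # self-loops count twice in degree
    two_m = k.sum()
    if two_m == 0:
        raise UndefinedModularityError("graph has zero total edge weight")
    same = comm[:, None] == comm[None, :]
    # A_ii enters the sum once; off-diagonal pairs enter twice via symmetry
    Afull = A + np.diag(np.diag(A))
    Q = np.sum((Afull - resolution * np.outer(k, k) / two_m) * same) / two_m
    return float(Q)


def _louvain_one_level(
    adj: list[dict[int, float]],
    self_w: np.ndarray,
    two_m: float,
    resolution: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Greedy local moving; returns the community of each node."""
    n = len(adj)
    k = np.array([sum(nb.values()) for nb in adj]) + 2.0 * self_w
    comm = np.arange(n)
    sigma_tot = k.copy()  # total degree per community
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            ci = comm[i]
            # weights from i to each neighbouring community
            w_to: dict[int, float] = {}
            for j, w in adj[i].items():
                w_to[comm[j]] = w_to.get(comm[j], 0.0) + w
            sigma_tot[ci] -= k[i]
            best_c, best_gain = ci, w_to.get(ci, 0.0) - resolution * sigma_tot[ci] * k[i] / two_m
            for c, w in w_to.items():
                if c == ci:
                    continue
                gain = w - resolution * sigma_tot[c] * k[i] / two_m
                if gain > best_gain + 1e-15 or (gain > best_gain - 1e-15 and c < best_c):
                    best_c, best_gain = c, gain
            sigma_tot[best_c] += k[i]
            if best_c != ci:
                comm[i] = best_c
                improved = True
    return comm


def _aggregate(
    adj: list[dict[int, float]], self_w: np.ndarray, comm: np.ndarray
) -> tuple[list[dict[int, float]], np.ndarray, np.ndarray]:
    labels, inv = np.unique(comm, return_inverse=True)
    nc = len(labels)
    new_adj: list[dict[int, float]] = [dict() for _ in range(nc)]
    new_self = np.zeros(nc)
    for i, nb in enumerate(adj):
        ci = inv[i]
        for j, w in nb.items():
            cj = inv[j]
            if ci == cj:
                if i < j:
                    new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
    new_self += np.bincount(inv, weights=self_w, minlength=nc)
    return new_adj, new_self, inv


def louvain(
    net,
    seed: int = DEFAULT_LOUVAIN_SEED,
    resolution: float = 1.0,
    min_gain: float = 1e-9,
) -> CommunityPartition:
    """Louvain community detection on a weighted undirected graph.

    Two-phase iteration: greedy local moving (each node relocated to the
    neighbouring community with maximal positive modularity gain until no
    move improves Q), then aggregation of communities into super-nodes;
    repeated until the modularity gain falls below ``min_gain``.  The node
    visit order is shuffled by ``seed`` — the only stochastic element.
    """
    A, nodes = _as_adjacency(net)
    rng = np.random.default_rng(seed)
    n = len(nodes)
    if n == 0:
        raise EmptyNetworkError("Louvain on an empty graph")
    adj = [
        {j: float(A[i, j]) for j in np.flatnonzero(A[i]) if j != i and A[i, j] != 0}
        for i in range(n)
    ]
    self_w = np.diag(A).astype(float).copy()
    k = np.array([sum(nb.values()) for nb in adj]) + 2.0 * self_w
    two_m = float(k.sum())
    if two_m == 0:
        raise UndefinedModularityError("graph has zero total edge weight")

    mapping = np.arange(n)  # original node -> current super-node
    assignment = {v: i for i, v in enumerate(nodes)}
    best_q = modularity(A, {i: c for i, c in enumerate(mapping)}, resolution)
    while True:
        comm = _louvain_one_level(adj, self_w, two_m, resolution, rng)
        adj, self_w, inv = _aggregate(adj, self_w, comm)
        mapping = inv[mapping]
        assignment = {v: int(mapping[i]) for i, v in enumerate(nodes)}
        q = modularity(A, {i: int(mapping[i]) for i in range(n)}, resolution)
        if q - best_q < min_gain:
            best_q = max(best_q, q)
            break
        best_q = q
        if len(self_w) == 1:
            break
    # renumber communities 0..K-1 in order of first appearance
    relabel: dict[int, int] = {}
    for v in nodes:
        relabel.setdefault(assignment[v], len(relabel))
    assignment = {v: relabel[assignment[v]] for v in nodes}
    return CommunityPartition(
        assignment=assignment, modularity=best_q, resolution=resolution, seed=seed
    )


class LouvainCommunities:
    """Estimator-style wrapper: ``fit`` a graph, read ``labels_`` and ``modularity_``.

    Follows the scikit-learn clustering idiom (get_params/set_params,
    trailing-underscore fitted attributes) over graph inputs.
    """

    def __init__(self, resolution: float = 1.0, seed: int = DEFAULT_LOUVAIN_SEED):
        self.resolution = resolution
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"resolution": self.resolution, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("resolution", "seed"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, net, y=None):
        part = louvain(net, seed=self.seed, resolution=self.resolution)
        _, nodes = _as_adjacency(net)
        self.nodes_ = list(nodes)
        self.labels_ = np.array([part.assignment[v] for v in nodes])
        self.modularity_ = part.modularity
        self.partition_ = part
        return self

    def fit_predict(self, net, y=None):
        return self.fit(net).labels_


def best_partition_exhaustive(net, resolution: float = 1.0) -> tuple[dict, float]:
    """Maximum-modularity partition by brute force over all set partitions.

    Only feasible for very small graphs (Bell(8) = 4140 partitions); used
    as an oracle for the Louvain heuristic on planted fixtures.
    """
    A, nodes = _as_adjacency(net)
    n = len(nodes)
    if n > 10:
        raise ValueError("exhaustive search limited to <= 10 nodes")

    best_q = -np.inf
    best: dict = {}

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
            yield [[first]] + smaller

    for part in partitions(list(range(n))):
        assignment = {}
        for c, block in enumerate(part):
            for i in block:
                assignment[nodes[i]] = c
        q = modularity(net, assignment, resolution)
        if q > best_q:
            best_q, best = q, assignment
    return best, float(best_q)


def sensitivity_sweep(
    panel: pd.DataFrame,
    thresholds: Sequence[float] = (0.0, 0.01, 0.02),
    schemes: Sequence[str] = ("joint_prevalence", "jaccard"),
    include_rare: bool = False,
    min_node_prevalence: float = 0.05,
    seed: int = DEFAULT_LOUVAIN_SEED,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Robustness sweep over edge thresholds, weight schemes and rare inclusion.

    The primary cell is (joint_prevalence, threshold 0, rare conditions
    excluded); every other cell reports its network metrics, Louvain
    partition, and the adjusted Rand index of its partition against the
    primary partition over the shared nodes.
    """
    from sklearn.metrics import adjusted_rand_score

    primary = build_network(
        panel, "joint_prevalence", min_node_prevalence, 0.0, conditions=conditions
    )
    primary_part = louvain(primary, seed=seed)

    rare_options = [False, True] if include_rare else [False]
    rows = []
    for scheme in schemes:
        for thr in thresholds:
            for rare in rare_options:
                mnp = 0.0 if rare else min_node_prevalence
                try:
                    net = build_network(panel, scheme, mnp, thr, conditions=conditions)
                    part = louvain(net, seed=seed)
                except EmptyNetworkError:
                    continue
                met = network_metrics(net)
                shared = [v for v in net.nodes if v in primary_part.assignment]
                if shared:
                    ari = adjusted_rand_score(
                        [primary_part.assignment[v] for v in shared],
                        [part.assignment[v] for v in shared],
                    )
                else:
                    ari = np.nan
                rows.append(
                    {
                        "scheme": scheme,
                        "edge_threshold": thr,
                        "include_rare": rare,
                        "n_nodes": met.n_nodes,
                        "n_edges": met.n_edges,
                        "density": met.density,
                        "clustering_coefficient": met.clustering_coefficient,
                        "diameter": met.diameter,
                        "n_communities": part.n_communities,
                        "modularity": part.modularity,
                        "ari_vs_primary": ari,
                    }
                )
    return pd.DataFrame(rows)
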