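"""Graph-theoretic features of binary connectivity networks.

Eight measures covering four aspects of network organisation:

* functional segregation — clustering coefficient, local efficiency;
* functional integration — characteristic path length, global efficiency;
* nodal centrality — degree, betweenness centrality, participation
  coefficient;
* resilience — average neighbor degree.

The six nodal measures (length m each) and the two global ones are
concatenated into a feature vector of length 6m + 2 (698 for a 116-region
atlas).  Conventions for degenerate nodes: clustering and local efficiency
are 0 for degree < 2; participation and average neighbor degree are 0 for
isolated nodes; the characteristic path length averages finite distances
only and is NaN (flagged) on an edgeless graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .models import BinaryNetwork, ConnectivityResults

__all__ = [
    "ModulePartition",
    "FeatureVector",
    "FEATURE_KINDS",
    "clustering_coefficient",
    "local_efficiency",
    "path_length_and_global_efficiency",
    "degree",
    "betweenness_centrality",
    "detect_modules",
    "participation_coefficient",
    "average_neighbor_degree",
    "modularity_score",
    "modularity_threshold_sweep",
    "extract_features",
    "feature_table",
]

NODAL_KINDS = (
    "clustering",
    "local_efficiency",
    "degree",
    "betweenness",
    "participation",
    "avg_neighbor_degree",
)
GLOBAL_KINDS = ("char_path_length", "global_efficiency")
FEATURE_KINDS = NODAL_KINDS + GLOBAL_KINDS


def _to_nx(g: BinaryNetwork) -> nx.Graph:
    G = nx.from_numpy_array(np.asarray(g.adjacency))
    return G


@dataclass(frozen=True)
class ModulePartition:
    """Node -> module assignment with contiguous ids starting at 0."""

    assignment: tuple[int, ...]
    method_tag: str = "greedy_modularity"

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment))
        if ids != list(range(len(ids))):
            raise ValueError("module ids must be contiguous from 0")
        object.__setattr__(self, "assignment", tuple(int(a) for a in self.assignment))

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment))

    def as_sets(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(self.n_modules)]
        for node, mod in enumerate(self.assignment):
            out[mod].add(node)
        return out


def clustering_coefficient(g: BinaryNetwork) -> np.ndarray:
    """C_i = 2 r_i / (k_i (k_i - 1)), 0 when the node has < 2 neighbors."""
    G = _to_nx(g)
    c = nx.clustering(G)
    return np.array([c[i] for i in range(g.n_nodes)], dtype=float)


def local_efficiency(g: BinaryNetwork) -> np.ndarray:
    """Average inverse shortest-path length among each node's neighbors.

    Paths are restricted to the neighborhood subgraph (the node itself
    removed); unreachable neighbor pairs contribute 0.
    """
    G = _to_nx(g)
    adj = np.asarray(g.adjacency)
    out = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = G.subgraph(nbrs)
        inv_sum = 0.0
        for j, lengths in nx.all_pairs_shortest_path_length(sub):
            for h, d in lengths.items():
                if h != j:
                    inv_sum += 1.0 / d
        out[i] = inv_sum / (k * (k - 1))
    return out


def path_length_and_global_efficiency(g: BinaryNetwork) -> tuple[float, float]:
    """Characteristic path length L and global efficiency E.

    L averages d_ij over the reachable ordered pairs only (infinite
    distances are excluded from both numerator and denominator); E uses
    1/inf = 0 over all pairs, so disconnection is handled naturally.  An
    edgeless graph has undefined L (NaN) and E = 0.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    G = _to_nx(g)
    if g.n_edges == 0:
        return float("nan"), 0.0
    dist_sum = 0.0
    inv_sum = 0.0
    n_finite = 0
    for i, lengths in nx.all_pairs_shortest_path_length(G):
        for j, d in lengths.items():
            if j != i:
                dist_sum += d
                inv_sum += 1.0 / d
                n_finite += 1
    L = dist_sum / n_finite
    E = inv_sum / (n * (n - 1))
    return float(L), float(E)


def degree(g: BinaryNetwork) -> np.ndarray:
    """k_i = number of links at node i (adjacency row sums)."""
    return np.asarray(g.adjacency).sum(axis=1).astype(float)


def betweenness_centrality(g: BinaryNetwork) -> np.ndarray:
    """Fraction of all shortest paths through each node.

    Normalised by (n-1)(n-2) over ordered endpoint pairs — equivalently the
    standard undirected normalisation — so a star center scores exactly 1.
    """
    if g.n_nodes < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    G = _to_nx(g)
    b = nx.betweenness_centrality(G, normalized=True)
    return np.array([b[i] for i in range(g.n_nodes)], dtype=float)


def detect_modules(g: BinaryNetwork) -> ModulePartition:
    """Deterministic greedy Newman-modularity agglomeration.

    Communities are relabelled 0,1,... by their smallest member so the
    partition is invariant to the library's internal ordering.  Edgeless
    graphs fall back to singleton modules.
    """
    n = g.n_nodes
    if g.n_edges == 0:
        return ModulePartition(assignment=tuple(range(n)), method_tag="singletons")
    G = _to_nx(g)
    communities = nx.community.greedy_modularity_communities(G)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    assignment = [0] * n
    for mod_id, members in enumerate(communities):
        for node in members:
            assignment[node] = mod_id
    return ModulePartition(assignment=tuple(assignment))


def participation_coefficient(g: BinaryNetwork, part: ModulePartition) -> np.ndarray:
    """y_i = 1 - sum_m (k_i(m) / k_i)^2; 0 for isolated nodes."""
    adj = np.asarray(g.adjacency, dtype=float)
    n = g.n_nodes
    if len(part.assignment) != n:
        raise ValueError("partition does not cover the graph")
    assign = np.asarray(part.assignment)
    k = adj.sum(axis=1)
    # per-node links into each module: n x n_modules
    links = np.zeros((n, part.n_modules))
    for mod in range(part.n_modules):
        links[:, mod] = adj[:, assign == mod].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = 1.0 - np.nansum((links / k[:, None]) ** 2, axis=1)
    y[k == 0] = 0.0
    return y


def average_neighbor_degree(g: BinaryNetwork) -> np.ndarray:
    """Mean degree of each node's neighbors; 0 for isolated nodes."""
    adj = np.asarray(g.adjacency, dtype=float)
    k = adj.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        knn = (adj @ k) / k
    knn[k == 0] = 0.0
    return knn


def modularity_score(g: BinaryNetwork, part: ModulePartition) -> float:
    """Newman modularity Q of a partition against the degree-preserving null."""
    if g.n_edges == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    G = _to_nx(g)
    return float(nx.community.modularity(G, part.as_sets()))


def modularity_threshold_sweep(
    res: ConnectivityResults, thresholds: list[float]
) -> list[tuple[float, float]]:
    """Modularity of the surviving network at each |weight| threshold.

    At each threshold, connections with |weight| < threshold are removed,
    the survivors binarized, modules detected, and Q computed; a threshold
    that empties the graph records NaN.  Averaging these per-subject curves
    across a cohort contrasts how modular each network model's estimates are.
    """
    w = res.weights
    if not np.allclose(w, w.T):
        raise ValueError("threshold sweep needs a symmetric matrix")
    curve = []
    for thr in thresholds:
        kept = np.where(np.abs(w) >= max(thr, 1e-10), 1, 0).astype(np.int8)
        np.fill_diagonal(kept, 0)
        net = BinaryNetwork(adjacency=kept)
        if net.n_edges == 0:
            curve.append((float(thr), float("nan")))
            continue
        part = detect_modules(net)
        curve.append((float(thr), modularity_score(net, part)))
    return curve


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated graph features of one subject's network.

    Layout: six nodal blocks of length m in the fixed order
    clustering | local_efficiency | degree | betweenness | participation |
    avg_neighbor_degree, followed by the two globals
    [char_path_length, global_efficiency].  Total length 6m + 2.
    """

    values: np.ndarray
    m: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (6 * self.m + 2,):
            raise ValueError(f"expected length {6 * self.m + 2}, got {vals.shape}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @staticmethod
    def describe_index(idx: int, m: int) -> tuple[str, int | None]:
        """Map a flat feature index to (kind, region index or None)."""
        if not 0 <= idx < 6 * m + 2:
            raise IndexError(idx)
        if idx >= 6 * m:
            return GLOBAL_KINDS[idx - 6 * m], None
        return NODAL_KINDS[idx // m], idx % m

    def block(self, kind: str) -> np.ndarray:
        if kind in GLOBAL_KINDS:
            return self.values[6 * self.m + GLOBAL_KINDS.index(kind) : 6 * self.m + GLOBAL_KINDS.index(kind) + 1]
        i = NODAL_KINDS.index(kind)
        return self.values[i * self.m : (i + 1) * self.m]


def extract_features(g: BinaryNetwork, subject_id: str = "") -> FeatureVector:
    """Compute all eight features and concatenate into one vector.

    An undefined characteristic path length (edgeless graph) is encoded as
    0.0 so the vector stays finite for classifiers.
    """
    part = detect_modules(g)
    L, E = path_length_and_global_efficiency(g)
    blocks = [
        clustering_coefficient(g),
        local_efficiency(g),
        degree(g),
        betweenness_centrality(g),
        participation_coefficient(g, part),
        average_neighbor_degree(g),
    ]
    values = np.concatenate(blocks + [[0.0 if np.isnan(L) else L, E]])
    return FeatureVector(values=values, m=g.n_nodes, subject_id=subject_id)


def feature_table(features: list[FeatureVector], region_labels: list[str]) -> pd.DataFrame:
    """Features x subjects table with named rows (kind:region)."""
    m = features[0].m
    index = [
        f"{kind}:{region_labels[r]}" for kind in NODAL_KINDS for r in range(m)
    ] + list(GLOBAL_KINDS)
    data = np.column_stack([f.values for f in features])
    cols = [f.subject_id or f"S{i:03d}" for i, f in enumerate(features)]
    return pd.DataFrame(data, index=index, columns=cols)
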