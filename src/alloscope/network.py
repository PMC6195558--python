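"""Dynamical network analysis.

A residue graph is built in three steps:

1. ``correlation_matrix`` - normalized motional correlations between
   Calpha nodes, C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) with dr the
   3-D displacement from the time-mean position (scalar dot-product
   convention, not per-axis Pearson).
2. ``contact_adjacency`` - an edge is allowed only between residues in
   persistent contact: any heavy-atom pair within ``cutoff`` in at least
   ``min_fraction`` of the window's frames, excluding trivial same-chain
   sequence neighbours.
3. ``build_network`` - contact edges are weighted w_ij = -log|C_ij| so
   strongly correlated contacts are short; communication is read from
   minimum-weight (Dijkstra) paths.

Communities come from the Girvan-Newman dendrogram (iterative removal of
the maximum edge-betweenness edge, betweenness recomputed after each
removal), retaining the partition that maximizes modularity. Modularity is
evaluated with correlation strength |C| as the edge affinity (modularity
expects an affinity, not a cost); this choice is configurable.

All tie-breaking is deterministic (lexicographic node/edge labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, InsufficientDataError
from .structure import ResidueSelection, Trajectory

__all__ = [
    "CorrelationMatrix",
    "ContactAdjacency",
    "CommunityPartition",
    "CommunicationPath",
    "CriticalEdge",
    "CriticalEdgeReport",
    "PathComparison",
    "correlation_matrix",
    "contact_adjacency",
    "build_network",
    "optimal_path",
    "girvan_newman_communities",
    "critical_edges",
    "path_length_compare",
    "write_graphml",
    "write_edge_csv",
    "write_partition_csv",
]

#: |C| is clamped to this floor before taking -log, keeping weights finite.
CORRELATION_FLOOR = 1e-8


@dataclass
class CorrelationMatrix:
    """Normalized motional correlations between residue nodes."""

    node_ids: list[str]
    matrix: np.ndarray
    valid: np.ndarray  # False for zero-variance (static) nodes

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.node_ids)
        if self.matrix.shape != (n, n):
            raise InputError("correlation matrix shape mismatch")
        finite = self.matrix[np.ix_(self.valid, self.valid)]
        if finite.size and np.nanmax(np.abs(finite)) > 1 + 1e-9:
            raise InputError("correlations must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class ContactAdjacency:
    """Persistent-contact adjacency between residue nodes."""

    node_ids: list[str]
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    contact_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)


@dataclass
class CommunityPartition:
    """node -> community id, with the partition's modularity."""

    assignment: dict[str, int]
    modularity: float

    def __post_init__(self) -> None:
        if not (-0.5 - 1e-9 <= self.modularity <= 1 + 1e-9):
            raise InputError("modularity outside [-0.5, 1]")

    def communities(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, set()).add(node)
        return [groups[c] for c in sorted(groups)]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class CommunicationPath:
    """An optimal (minimum total weight) communication path."""

    nodes: list[str] | None
    total_weight: float
    edge_weights: list[float] = field(default_factory=list)

    @property
    def connected(self) -> bool:
        return self.nodes is not None


@dataclass
class CriticalEdge:
    node_a: str
    node_b: str
    community_a: int
    community_b: int
    weight: float
    betweenness: float
    is_top_for_pair: bool


@dataclass
class CriticalEdgeReport:
    edges: list[CriticalEdge]

    def top_edges(self) -> list[CriticalEdge]:
        return [e for e in self.edges if e.is_top_for_pair]


def node_id(chain: str, resnum: int) -> str:
    return f"{chain}:{resnum}"


def _node_metadata(trajectory: Trajectory, selection: ResidueSelection):
    topo = trajectory.topology
    res_idx = [int(topo.atom_resindex[i]) for i in selection.atom_indices]
    ids = [node_id(str(topo.res_chains[r]), int(topo.res_numbers[r])) for r in res_idx]
    meta = [
        {
            "chain": str(topo.res_chains[r]),
            "resnum": int(topo.res_numbers[r]),
            "resname": str(topo.res_names[r]),
        }
        for r in res_idx
    ]
    return ids, meta, res_idx


def correlation_matrix(
    trajectory: Trajectory,
    nodes: ResidueSelection,
    window: tuple[int, int] | None = None,
) -> CorrelationMatrix:
    """Motional correlation between Calpha nodes over a frame window.

    The trajectory should be superposed over the node set so the
    displacements measure internal motion, not global drift. Static
    (zero-variance) nodes are flagged invalid; their correlations are NaN
    and they acquire no edges downstream.
    """
    if len(nodes.atom_indices) != len(nodes.residue_indices):
        raise InputError("correlation nodes must be one atom per residue")
    start, stop = trajectory.frame_range(window)
    if stop - start < 2:
        raise InsufficientDataError("correlations need >= 2 frames")
    coords = trajectory.coordinates[start:stop, nodes.atom_indices, :]
    disp = coords - coords.mean(axis=0, keepdims=True)
    n_frames, n_nodes = disp.shape[0], disp.shape[1]
    # <dr_i . dr_j> via a (nodes, frames*3) Gram matrix
    flat = np.ascontiguousarray(disp.transpose(1, 0, 2).reshape(n_nodes, n_frames * 3))
    cov = flat @ flat.T / n_frames
    var = np.diag(cov).copy()
    valid = var > 1e-12
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / denom
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    ids, _, _ = _node_metadata(trajectory, nodes)
    return CorrelationMatrix(ids, corr, valid)


def contact_adjacency(
    trajectory: Trajectory,
    nodes: ResidueSelection,
    contact_atoms: ResidueSelection | None = None,
    cutoff: float = 4.5,
    min_fraction: float = 0.75,
    neighbor_exclusion: int = 1,
    window: tuple[int, int] | None = None,
) -> ContactAdjacency:
    """Persistent-contact adjacency between the node residues.

    Two residues are adjacent when any pair of their contact atoms (default:
    the node atoms themselves; pass a heavy-atom selection of the same
    residues for the all-heavy-atom criterion) lies within ``cutoff`` in at
    least ``min_fraction`` of the window's frames. Same-chain sequence
    neighbours with |i - j| <= ``neighbor_exclusion`` are excluded.
    """
    topo = trajectory.topology
    ids, _, node_res = _node_metadata(trajectory, nodes)
    res_to_node = {r: k for k, r in enumerate(node_res)}
    atoms = (contact_atoms or nodes).atom_indices
    atoms = np.array(
        [a for a in atoms if int(topo.atom_resindex[a]) in res_to_node], dtype=int
    )
    atom_node = np.array([res_to_node[int(topo.atom_resindex[a])] for a in atoms])

    start, stop = trajectory.frame_range(window)
    n_frames = stop - start
    n_nodes = len(ids)
    counts = np.zeros((n_nodes, n_nodes), dtype=np.int32)
    for f in range(start, stop):
        tree = cKDTree(trajectory.coordinates[f][atoms])
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ni = atom_node[pairs[:, 0]]
        nj = atom_node[pairs[:, 1]]
        mask = ni != nj
        if not mask.any():
            continue
        lo = np.minimum(ni[mask], nj[mask])
        hi = np.maximum(ni[mask], nj[mask])
        seen = np.unique(lo.astype(np.int64) * n_nodes + hi)
        counts[seen // n_nodes, seen % n_nodes] += 1

    fraction = counts / float(n_frames)
    adjacency = fraction >= min_fraction
    adjacency |= adjacency.T
    fraction = np.maximum(fraction, fraction.T)
    # sequence-neighbour exclusion on the same chain
    chains = np.array([topo.res_chains[r] for r in node_res], dtype=object)
    numbers = np.array([topo.res_numbers[r] for r in node_res], dtype=int)
    same_chain = chains[:, None] == chains[None, :]
    close_seq = np.abs(numbers[:, None] - numbers[None, :]) <= neighbor_exclusion
    adjacency &= ~(same_chain & close_seq)
    np.fill_diagonal(adjacency, False)
    return ContactAdjacency(ids, adjacency, fraction)


def build_network(
    adjacency: ContactAdjacency,
    correlations: CorrelationMatrix,
) -> nx.Graph:
    """Correlation-weighted residue graph.

    Each contact edge carries ``weight`` = -log(|C_ij|) (|C| clamped to
    [1e-8, 1]) and ``affinity`` = |C_ij|. Invalid (static) nodes get no
    edges. The graph may be disconnected.
    """
    if adjacency.node_ids != correlations.node_ids:
        raise InputError("adjacency and correlations carry different node sets")
    graph = nx.Graph()
    for nid in adjacency.node_ids:
        graph.add_node(nid)
    n = len(adjacency.node_ids)
    for i in range(n):
        if not correlations.valid[i]:
            continue
        for j in range(i + 1, n):
            if not adjacency.adjacency[i, j] or not correlations.valid[j]:
                continue
            c = abs(float(correlations.matrix[i, j]))
            c = min(max(c, CORRELATION_FLOOR), 1.0)
            graph.add_edge(
                adjacency.node_ids[i],
                adjacency.node_ids[j],
                weight=float(-np.log(c)),
                affinity=c,
                correlation=float(correlations.matrix[i, j]),
            )
    return graph


def optimal_path(graph: nx.Graph, source: str, target: str) -> CommunicationPath:
    """Minimum-total-weight path (Dijkstra, lexicographic tie-breaking).

    Returns an explicit no-path result when source and target are
    disconnected.
    """
    if source == target:
        raise InputError("source and target must differ")
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"node {node!r} not in graph")
    try:
        paths = nx.all_shortest_paths(graph, source, target, weight="weight")
        best = min(paths)  # deterministic: lexicographically smallest node list
    except nx.NetworkXNoPath:
        return CommunicationPath(None, float("inf"))
    edge_weights = [
        float(graph[u][v]["weight"]) for u, v in zip(best, best[1:])
    ]
    return CommunicationPath(list(best), float(sum(edge_weights)), edge_weights)


def _max_betweenness_edge(graph: nx.Graph) -> tuple[str, str]:
    """Edge to remove next: maximum affinity-normalized betweenness.

    Betweenness is computed on the weighted (distance) graph; dividing by
    the edge's affinity |C| (the weighted Girvan-Newman criterion) makes
    weak inter-community edges outrank strong intra-community edges even
    when a community relays traffic between two others. Ties break on the
    lexicographically smallest edge.
    """
    bt = nx.edge_betweenness_centrality(graph, weight="weight")
    scores = {
        e: v / graph.edges[e].get("affinity", 1.0) for e, v in bt.items()
    }
    best_val = max(scores.values())
    candidates = [
        tuple(sorted(e)) for e, v in scores.items() if v >= best_val * (1 - 1e-12)
    ]
    return min(candidates)


def _components_partition(graph: nx.Graph) -> dict[str, int]:
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    return {node: cid for cid, comp in enumerate(comps) for node in comp}


def _partition_modularity(graph: nx.Graph, assignment: dict[str, int]) -> float:
    """Modularity with |C| affinities as edge weights; 0 for edgeless graphs."""
    if graph.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set[str]] = {}
    for node, cid in assignment.items():
        groups.setdefault(cid, set()).add(node)
    return float(
        nx.community.modularity(graph, list(groups.values()), weight="affinity")
    )


def girvan_newman_communities(
    graph: nx.Graph,
    max_removals: int | None = None,
    patience: int | None = None,
) -> CommunityPartition:
    """Girvan-Newman communities, keeping the maximum-modularity partition.

    The maximum edge-betweenness edge (weighted betweenness, recomputed
    after every removal) is removed iteratively; each time the component
    structure changes, the partition's modularity is evaluated on the
    original graph with |C| affinities. Ties keep the earlier (coarser)
    partition. ``max_removals``/``patience`` bound the dendrogram descent
    for large graphs; both default to a full descent, which exhaustive
    small-graph oracles require.
    """
    if graph.number_of_edges() == 0:
        assignment = {node: i for i, node in enumerate(sorted(graph.nodes))}
        return CommunityPartition(assignment, 0.0)
    best_assignment = _components_partition(graph)
    best_q = _partition_modularity(graph, best_assignment)
    work = graph.copy()
    n_components = nx.number_connected_components(work)
    removals = 0
    since_improvement = 0
    while work.number_of_edges():
        if max_removals is not None and removals >= max_removals:
            break
        if patience is not None and since_improvement >= patience:
            break
        work.remove_edge(*_max_betweenness_edge(work))
        removals += 1
        since_improvement += 1
        new_n = nx.number_connected_components(work)
        if new_n != n_components:
            n_components = new_n
            assignment = _components_partition(work)
            q = _partition_modularity(graph, assignment)
            if q > best_q + 1e-12:
                best_q, best_assignment = q, assignment
                since_improvement = 0
    return CommunityPartition(best_assignment, best_q)


def critical_edges(
    graph: nx.Graph, partition: CommunityPartition
) -> CriticalEdgeReport:
    """Inter-community edges ranked by betweenness.

    The top edge per community pair is labelled critical; its endpoints are
    the critical nodes joining those communities. Empty for a single
    community.
    """
    missing = set(graph.nodes) - set(partition.assignment)
    if missing:
        raise InputError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    bt = nx.edge_betweenness_centrality(graph, weight="weight")
    rows = []
    for (u, v), b in bt.items():
        cu, cv = partition.assignment[u], partition.assignment[v]
        if cu == cv:
            continue
        a, bnode = sorted((u, v))
        ca, cb = sorted((cu, cv))
        rows.append((ca, cb, -b, a, bnode, float(graph[u][v]["weight"]), float(b)))
    rows.sort()
    edges: list[CriticalEdge] = []
    seen_pairs: set[tuple[int, int]] = set()
    for ca, cb, _negb, a, bnode, w, b in rows:
        top = (ca, cb) not in seen_pairs
        seen_pairs.add((ca, cb))
        edges.append(CriticalEdge(a, bnode, ca, cb, w, b, top))
    return CriticalEdgeReport(edges)


@dataclass
class PathComparison:
    """Side-by-side optimal paths of two graphs for one source/target pair."""

    path_a: CommunicationPath
    path_b: CommunicationPath
    weight_difference: float  # b - a (inf-aware)
    node_count_difference: int | None
    verdict: str  # 'longer', 'shorter' or 'equal' (b relative to a)


def path_length_compare(
    graph_a: nx.Graph, graph_b: nx.Graph, source: str, target: str
) -> PathComparison:
    """Compare optimal source->target paths between two networks.

    Missing nodes or disconnection are reported as an infinite-length side
    rather than raising.
    """

    def safe_path(graph: nx.Graph) -> CommunicationPath:
        if source not in graph or target not in graph:
            return CommunicationPath(None, float("inf"))
        return optimal_path(graph, source, target)

    pa, pb = safe_path(graph_a), safe_path(graph_b)
    if np.isinf(pa.total_weight) and np.isinf(pb.total_weight):
        diff, verdict = 0.0, "equal"
    else:
        diff = pb.total_weight - pa.total_weight
        verdict = "equal" if abs(diff) < 1e-12 else ("longer" if diff > 0 else "shorter")
    ncd = (
        len(pb.nodes) - len(pa.nodes)
        if (pa.connected and pb.connected)
        else None
    )
    return PathComparison(pa, pb, float(diff), ncd, verdict)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edge_csv(
    graph: nx.Graph,
    path,
    partition: CommunityPartition | None = None,
    betweenness: dict | None = None,
) -> None:
    """Edge list CSV: node_i, node_j, correlation, weight, betweenness, communities."""
    import pandas as pd

    bt = betweenness or nx.edge_betweenness_centrality(graph, weight="weight")
    rows = []
    for u, v, data in sorted(graph.edges(data=True)):
        rows.append(
            {
                "node_i": u,
                "node_j": v,
                "correlation": data.get("correlation"),
                "weight": data.get("weight"),
                "betweenness": bt.get((u, v), bt.get((v, u))),
                "community_i": partition.assignment[u] if partition else None,
                "community_j": partition.assignment[v] if partition else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_partition_csv(partition: CommunityPartition, path) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["node", "community"]
    ).to_csv(path, index=False)
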