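"""Shared helpers: tiny in-memory systems and independent oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from alloscope.structure import ResidueSelection, Topology, Trajectory


def make_topology(
    atoms: list[tuple[str, str, str, int, str]],
    masses: dict[str, float] | None = None,
) -> Topology:
    """Build a Topology from (atom_name, element, chain, resnum, resname) rows.

    Consecutive rows with the same (chain, resnum) form one residue.
    """
    default_masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
    masses = masses or default_masses
    res_keys: list[tuple[str, int, str]] = []
    atom_resindex = []
    for name, element, chain, resnum, resname in atoms:
        key = (chain, resnum, resname)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex.append(len(res_keys) - 1)
    return Topology(
        atom_names=np.array([a[0] for a in atoms], dtype=object),
        elements=np.array([a[1] for a in atoms], dtype=object),
        masses=np.array([masses[a[1]] for a in atoms]),
        atom_resindex=np.array(atom_resindex),
        res_numbers=np.array([k[1] for k in res_keys]),
        res_names=np.array([k[2] for k in res_keys], dtype=object),
        res_chains=np.array([k[0] for k in res_keys], dtype=object),
    )


def make_trajectory(
    topology: Topology, coords: np.ndarray, dt_ns: float = 1.0
) -> Trajectory:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    times = np.arange(coords.shape[0]) * dt_ns
    return Trajectory(topology, coords, times)


def full_selection(topology: Topology, domain: str = "all") -> ResidueSelection:
    return ResidueSelection(
        np.arange(topology.n_atoms), domain, np.arange(topology.n_residues)
    )


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans


# --- graph oracles ---------------------------------------------------------


def enumerate_simple_paths(graph: nx.Graph, source, target):
    """All simple source->target paths by explicit DFS (independent of
    networkx path routines)."""
    paths = []
    stack = [(source, [source])]
    while stack:
        node, path = stack.pop()
        if node == target:
            paths.append(path)
            continue
        for nbr in graph[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr]))
    return paths


def brute_force_shortest(graph: nx.Graph, source, target):
    """(min total weight, all optimal node lists) by path enumeration."""
    best = float("inf")
    optimal = []
    for path in enumerate_simple_paths(graph, source, target):
        w = sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
        if w < best - 1e-12:
            best, optimal = w, [path]
        elif abs(w - best) <= 1e-12:
            optimal.append(path)
    return best, optimal


def brute_force_edge_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized weighted edge betweenness by shortest-path enumeration."""
    bt = {tuple(sorted(e)): 0.0 for e in graph.edges}
    for s, t in itertools.combinations(sorted(graph.nodes), 2):
        best, optimal = brute_force_shortest(graph, s, t)
        if not optimal:
            continue
        share = 1.0 / len(optimal)
        for path in optimal:
            for u, v in zip(path, path[1:]):
                bt[tuple(sorted((u, v)))] += share
    return bt


def weighted_modularity(graph: nx.Graph, blocks, weight: str = "affinity") -> float:
    """Newman weighted modularity of a partition (fast closed form)."""
    m2 = 2.0 * sum(d.get(weight, 1.0) for _u, _v, d in graph.edges(data=True))
    if m2 == 0:
        return 0.0
    community_of = {}
    for i, block in enumerate(blocks):
        for node in block:
            community_of[node] = i
    q = 0.0
    degrees = dict.fromkeys(graph.nodes, 0.0)
    for u, v, d in graph.edges(data=True):
        w = d.get(weight, 1.0)
        degrees[u] += w
        degrees[v] += w
        if community_of[u] == community_of[v]:
            q += 2.0 * w / m2
    for block in blocks:
        d_c = sum(degrees[n] for n in block)
        q -= (d_c / m2) ** 2
    return q


def set_partitions(items):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def exhaustive_best_modularity(graph: nx.Graph, weight: str = "affinity"):
    """Maximum modularity over every partition of the node set."""
    best_q, best_blocks = -1.0, None
    for blocks in set_partitions(sorted(graph.nodes)):
        q = weighted_modularity(graph, blocks, weight)
        if q > best_q + 1e-12:
            best_q, best_blocks = q, blocks
    return best_q, best_blocks
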