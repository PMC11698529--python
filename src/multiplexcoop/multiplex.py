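"""Two-layer multiplex networks with controllable edge overlap.

A multiplex network is a set of layers, each an undirected simple graph
over the same ``N`` nodes.  The average edge overlap

    O_{a,b} = |E^a ∩ E^b| / |E^a ∪ E^b|,   O = mean over layer pairs,

quantifies structural similarity between layers: ``O = 1`` for identical
layers, ``O = 0`` for edge-disjoint ones.  Generation builds layer 1
(random-regular, scale-free or complete), copies it into layer 2, and
then applies degree-preserving double-edge swaps to layer 2, accepting
only swaps that move the measured overlap toward the target.  This keeps
both layers' degree sequences identical while reaching any overlap in
``[0, 1]`` up to a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "MultiplexNetwork",
    "OverlapReport",
    "generate_multiplex",
    "average_edge_overlap",
    "layer_pair_overlap",
    "overlap_report",
    "neighbor_partition",
    "read_multiplex_edgelist",
    "write_multiplex_edgelist",
]


def _canon_edges(edges) -> set[tuple[int, int]]:
    return {(min(u, v), max(u, v)) for u, v in edges}


class MultiplexNetwork:
    """Undirected, unweighted multiplex network over a shared node set.

    Parameters
    ----------
    layer_edges
        One edge collection per layer; pairs are unordered, self-loops
        forbidden.
    n_nodes
        Number of nodes (node ids are ``0 .. n_nodes-1`` in every layer).
    seed
        Seed used during construction, echoed for provenance.
    """

    def __init__(self, layer_edges: Sequence, n_nodes: int, seed: int | None = None):
        if n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        self.n_nodes = int(n_nodes)
        self.seed = seed
        self._edge_sets: list[set[tuple[int, int]]] = []
        for li, edges in enumerate(layer_edges):
            canon = _canon_edges(edges)
            for u, v in canon:
                if u == v:
                    raise ValueError(f"self-loop {u}-{v} in layer {li + 1}")
                if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                    raise ValueError(f"node id out of range in layer {li + 1}: ({u}, {v})")
            self._edge_sets.append(canon)
        if not self._edge_sets:
            raise ValueError("at least one layer required")

    @property
    def n_layers(self) -> int:
        return len(self._edge_sets)

    def edge_set(self, layer: int) -> set[tuple[int, int]]:
        """Edges of one layer as canonical ``(min, max)`` pairs."""
        return set(self._edge_sets[layer])

    def edges(self, layer: int) -> np.ndarray:
        """Edge array of one layer, shape ``(E, 2)``, canonical order."""
        es = sorted(self._edge_sets[layer])
        if not es:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(es, dtype=np.int64)

    def adjacency(self, layer: int) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix of one layer."""
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        e = self.edges(layer)
        if len(e):
            A[e[:, 0], e[:, 1]] = 1
            A[e[:, 1], e[:, 0]] = 1
        return A

    def degrees(self, layer: int) -> np.ndarray:
        """Per-node degree vector in one layer."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        e = self.edges(layer)
        if len(e):
            np.add.at(deg, e[:, 0], 1)
            np.add.at(deg, e[:, 1], 1)
        return deg

    def neighbors(self, node: int, layer: int) -> set[int]:
        out = set()
        for u, v in self._edge_sets[layer]:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def graph(self, layer: int) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self._edge_sets[layer])
        return g

    def __repr__(self) -> str:  # pragma: no cover
        sizes = ", ".join(str(len(s)) for s in self._edge_sets)
        return f"MultiplexNetwork(N={self.n_nodes}, layers={self.n_layers}, |E|=[{sizes}])"


@dataclass
class OverlapReport:
    """Overlap statistics of a multiplex network.

    Attributes
    ----------
    o_ij
        Per-pair edge overlap matrix, ``o_ij = (1/m) sum_a A_ij^a``.
    layer_pair_overlap
        Jaccard overlap ``O_{a,b}`` for every layer pair, keyed
        ``(a, b)`` with ``a < b``.
    average_overlap
        Mean of the layer-pair overlaps.
    common_count
        ``O_i^CN``: per-node number of common neighbors (2-layer case).
    unique_count
        ``O_{i,a}^UN``: per-node unique-neighbor counts, shape ``(m, N)``.
    """

    o_ij: np.ndarray
    layer_pair_overlap: dict
    average_overlap: float
    common_count: np.ndarray
    unique_count: np.ndarray


def layer_pair_overlap(net: MultiplexNetwork, a: int, b: int) -> float:
    """Jaccard edge overlap between layers ``a`` and ``b``."""
    ea, eb = net.edge_set(a), net.edge_set(b)
    union = len(ea | eb)
    if union == 0:
        raise ValueError("edge overlap undefined: both layers empty")
    return len(ea & eb) / union


def average_edge_overlap(net: MultiplexNetwork) -> float:
    """Average Jaccard edge overlap over all layer pairs."""
    if net.n_layers < 2:
        raise ValueError("average edge overlap requires at least two layers")
    vals = [
        layer_pair_overlap(net, a, b)
        for a in range(net.n_layers)
        for b in range(a + 1, net.n_layers)
    ]
    return float(np.mean(vals))


def overlap_report(net: MultiplexNetwork) -> OverlapReport:
    """Compute per-pair, per-node and average overlap statistics."""
    m, N = net.n_layers, net.n_nodes
    adj = np.stack([net.adjacency(a) for a in range(m)]).astype(float)
    o_ij = adj.mean(axis=0)
    pair = {
        (a, b): layer_pair_overlap(net, a, b)
        for a in range(m)
        for b in range(a + 1, m)
    }
    # per-node counts use the 2-layer definition (common across all layers)
    common_mask = np.all(adj > 0, axis=0)
    common_count = common_mask.sum(axis=1).astype(np.int64)
    unique_count = np.stack(
        [(adj[a] > 0).sum(axis=1) - common_count for a in range(m)]
    ).astype(np.int64)
    return OverlapReport(
        o_ij=o_ij,
        layer_pair_overlap=pair,
        average_overlap=float(np.mean(list(pair.values()))),
        common_count=common_count,
        unique_count=unique_count,
    )


def neighbor_partition(net: MultiplexNetwork, node: int, layer: int) -> tuple[set, set]:
    """Split a node's layer-``layer`` neighbors into (common, unique).

    Common neighbors are connected to ``node`` in every layer; unique
    neighbors only in ``layer``.
    """
    if not (0 <= node < net.n_nodes):
        raise IndexError(f"node {node} out of range")
    if not (0 <= layer < net.n_layers):
        raise IndexError(f"layer {layer} out of range")
    nbrs = net.neighbors(node, layer)
    common = set(nbrs)
    for other in range(net.n_layers):
        if other != layer:
            common &= net.neighbors(node, other)
    return common, nbrs - common


# ---------------------------------------------------------------------------
# generation


def _layer_graph(topology: str, n_nodes: int, degree_param: int, rng: np.random.Generator) -> nx.Graph:
    if topology == "rrn":
        if degree_param >= n_nodes:
            raise ValueError("rrn requires degree < n_nodes")
        if (n_nodes * degree_param) % 2 != 0:
            raise ValueError("rrn requires n_nodes * degree to be even")
        return nx.random_regular_graph(degree_param, n_nodes, seed=int(rng.integers(2**31)))
    if topology == "sfn":
        # preferential attachment with m = degree_param / 2 gives mean degree
        # ~degree_param for large N
        m_attach = max(1, degree_param // 2)
        return nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31)))
    if topology == "complete":
        return nx.complete_graph(n_nodes)
    raise ValueError(f"unknown topology {topology!r}")


def generate_multiplex(
    topology: str,
    n_nodes: int,
    degree_param: int,
    target_overlap: float,
    seed: int | None = None,
    *,
    tol: float = 0.02,
    swap_budget_factor: int = 200,
) -> MultiplexNetwork:
    """Generate a 2-layer multiplex with a target average edge overlap.

    Layer 1 is drawn from the requested topology, layer 2 starts as an
    exact copy and is rewired with degree-preserving double-edge swaps,
    accepting a swap only when it moves the shared-edge count toward the
    target.  Per-node degrees in layer 2 therefore equal those of
    layer 1 exactly.

    Raises ``ValueError`` for infeasible parameters and ``RuntimeError``
    if the swap budget (``swap_budget_factor * |E|`` attempts) is
    exhausted before the measured overlap is within ``tol`` of the
    target.
    """
    if not (0.0 <= target_overlap <= 1.0):
        raise ValueError("target_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g1 = _layer_graph(topology, n_nodes, degree_param, rng)
    edges1 = sorted(_canon_edges(g1.edges()))
    if topology == "complete":
        # the complete graph is the unique graph with its degree sequence
        return MultiplexNetwork([edges1, list(edges1)], n_nodes, seed=seed)

    E = len(edges1)
    if E == 0:
        raise ValueError("layer 1 has no edges")
    e1_set = set(edges1)
    edges2 = list(edges1)
    e2_set = set(edges2)

    # overlap O = I / (2E - I) is monotone in the intersection size I,
    # so steer I toward the target intersection
    target_I = target_overlap * 2 * E / (1.0 + target_overlap)

    def measured(I: int) -> float:
        return I / (2 * E - I)

    I = E
    budget = swap_budget_factor * E
    attempts = 0
    while abs(measured(I) - target_overlap) > tol and attempts < budget:
        attempts += 1
        i, j = rng.integers(0, E, size=2)
        if i == j:
            continue
        a, b = edges2[i]
        c, d = edges2[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in e2_set or new2 in e2_set or new1 == new2:
            continue
        old1, old2 = edges2[i], edges2[j]
        dI = (
            (new1 in e1_set) + (new2 in e1_set)
            - (old1 in e1_set) - (old2 in e1_set)
        )
        newdist = abs(I + dI - target_I)
        curdist = abs(I - target_I)
        if newdist > curdist or (newdist == curdist and rng.random() < 0.5):
            continue
        e2_set.discard(old1)
        e2_set.discard(old2)
        e2_set.add(new1)
        e2_set.add(new2)
        edges2[i] = new1
        edges2[j] = new2
        I += dI
    if abs(measured(I) - target_overlap) > tol:
        raise RuntimeError(
            f"overlap target {target_overlap} unreachable within tolerance {tol} "
            f"after {attempts} swap attempts (measured {measured(I):.4f})"
        )
    return MultiplexNetwork([edges1, sorted(e2_set)], n_nodes, seed=seed)


# ---------------------------------------------------------------------------
# edge-list I/O: plain-text lines "layer u v", layers 1-based in files


def read_multiplex_edgelist(path, n_layers: int | None = None) -> MultiplexNetwork:
    """Read a multilayer edge list (``layer u v`` per line).

    Whitespace- or comma-separated; blank lines and ``#`` comments are
    ignored; duplicate edges collapse; node labels may be arbitrary
    strings and are mapped to contiguous 0-based indices in order of
    first appearance.  Layer ids are 1-based in the file.  Self-loops
    are rejected, as are layer ids beyond ``n_layers`` when given.
    """
    path = Path(path)
    label_to_idx: dict[str, int] = {}
    layer_edges: dict[int, set] = {}

    def node_idx(label: str) -> int:
        if label not in label_to_idx:
            label_to_idx[label] = len(label_to_idx)
        return label_to_idx[label]

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'layer u v', got {raw!r}")
        layer = int(parts[0])
        if layer < 1:
            raise ValueError(f"{path}:{lineno}: layer ids are 1-based, got {layer}")
        if n_layers is not None and layer > n_layers:
            raise ValueError(f"{path}:{lineno}: layer {layer} beyond declared {n_layers}")
        u, v = node_idx(parts[1]), node_idx(parts[2])
        if u == v:
            raise ValueError(f"{path}:{lineno}: self-loop on node {parts[1]!r}")
        layer_edges.setdefault(layer, set()).add((min(u, v), max(u, v)))
    if not layer_edges:
        raise ValueError(f"{path}: no edges found")
    m = n_layers if n_layers is not None else max(layer_edges)
    n_nodes = len(label_to_idx)
    return MultiplexNetwork(
        [sorted(layer_edges.get(a, set())) for a in range(1, m + 1)], n_nodes
    )


def write_multiplex_edgelist(net: MultiplexNetwork, path) -> None:
    """Write a multiplex as ``layer u v`` lines (layers 1-based)."""
    lines = ["# multiplex edge list: layer u v"]
    for a in range(net.n_layers):
        for u, v in sorted(net.edge_set(a)):
            lines.append(f"{a + 1} {u} {v}")
    Path(path).write_text("\n".join(lines) + "\n")
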