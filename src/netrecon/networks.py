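"""Sparse, modular, signed, directed reference networks.

The benchmark's ground truth is a directed graph over ``n`` nodes whose
adjacency matrix takes values in {-1, 0, +1}: entry ``(i, j)`` is nonzero
when node ``j`` regulates node ``i`` (+1 activation, -1 inhibition).
Generated networks mimic three topological properties commonly reported for
biological regulatory networks — sparseness, a right-skewed (hub-biased)
out-degree distribution, and modular clustering — without reproducing any
particular simulator's exact algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignedNetwork",
    "generate_network",
    "edge_density",
    "edge_count_for_density",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
]


@dataclass
class SignedNetwork:
    """Directed signed graph stored as a dense integer adjacency matrix.

    Parameters
    ----------
    adjacency : ndarray of shape (n, n)
        Integer matrix over {-1, 0, +1}. ``adjacency[i, j] != 0`` means node
        ``j`` regulates node ``i``.
    node_labels : list of str, optional
        Defaults to ``g1 .. gn``.
    """

    adjacency: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(adj, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        self.adjacency = adj.astype(int)
        if not self.node_labels:
            self.node_labels = [f"g{i + 1}" for i in range(adj.shape[0])]
        if len(self.node_labels) != adj.shape[0]:
            raise ValueError("node_labels length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero off-diagonal entries."""
        off = self.adjacency.copy()
        np.fill_diagonal(off, 0)
        return int(np.count_nonzero(off))

    def edges(self, include_diagonal: bool = False) -> list[tuple[int, int, int]]:
        """List of ``(source, target, sign)`` tuples (0-based indices)."""
        out = []
        for i, j in zip(*np.nonzero(self.adjacency)):
            if i == j and not include_diagonal:
                continue
            # adjacency[i, j]: j -> i
            out.append((int(j), int(i), int(self.adjacency[i, j])))
        return sorted(out)

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(self.adjacency.copy(), list(self.node_labels))


def edge_density(network: SignedNetwork) -> float:
    """Fraction E / (N * (N - 1)) of possible directed edges present.

    Self-loops are excluded from both numerator and denominator.
    """
    n = network.n_nodes
    if n < 2:
        raise ValueError("edge density requires at least 2 nodes")
    return network.n_edges / (n * (n - 1))


def edge_count_for_density(n_nodes: int, density: float) -> int:
    """Edge count realizing a requested density, rounded half-to-even."""
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    return int(np.round(density * n_nodes * (n_nodes - 1)))


def _module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    # round-robin partition: node i -> module i mod n_modules
    return np.arange(n_nodes) % n_modules


def generate_network(
    n_nodes: int,
    n_edges: int,
    n_modules: int = 3,
    p_inhibition: float = 0.3,
    seed: int = 0,
    intra_module_p: float = 0.8,
) -> SignedNetwork:
    """Generate a random sparse modular signed directed network.

    Edges are placed one at a time. Sources are drawn with probability
    proportional to (current out-degree + 1), a preferential-attachment rule
    that yields a right-skewed, hub-biased out-degree distribution. Targets
    fall inside the source's module with probability ``intra_module_p``,
    producing modular clustering. Each edge is inhibitory (-1) independently
    with probability ``p_inhibition``, activating (+1) otherwise. No
    self-loops are produced.

    Deterministic for identical arguments.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    if n_edges < 0:
        raise ValueError("n_edges must be non-negative")
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges={n_edges} exceeds capacity {max_edges} for {n_nodes} nodes"
        )
    if n_modules < 1 or n_modules > n_nodes:
        raise ValueError("n_modules must be in [1, n_nodes]")
    if not 0 <= p_inhibition <= 1:
        raise ValueError("p_inhibition must be in [0, 1]")

    rng = np.random.default_rng(seed)
    modules = _module_assignment(n_nodes, n_modules)
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    out_degree = np.zeros(n_nodes, dtype=float)

    placed = 0
    stall = 0
    while placed < n_edges:
        if stall > 50 * n_nodes:
            # dense regime: fill uniformly from remaining free slots
            free = [
                (i, j)
                for i in range(n_nodes)
                for j in range(n_nodes)
                if i != j and adj[i, j] == 0
            ]
            pick = rng.choice(len(free), size=n_edges - placed, replace=False)
            for idx in pick:
                i, j = free[int(idx)]
                adj[i, j] = 1
            placed = n_edges
            break
        weights = out_degree + 1.0
        src = int(rng.choice(n_nodes, p=weights / weights.sum()))
        same = np.flatnonzero((modules == modules[src]) & (np.arange(n_nodes) != src))
        other = np.flatnonzero(modules != modules[src])
        if same.size and (not other.size or rng.random() < intra_module_p):
            tgt = int(rng.choice(same))
        elif other.size:
            tgt = int(rng.choice(other))
        else:
            stall += 1
            continue
        if adj[tgt, src] != 0:
            stall += 1
            continue
        adj[tgt, src] = 1
        out_degree[src] += 1
        placed += 1
        stall = 0

    signs = np.where(rng.random(n_edges) < p_inhibition, -1, 1)
    rows, cols = np.nonzero(adj)
    order = np.lexsort((cols, rows))
    for k, idx in enumerate(order):
        adj[rows[idx], cols[idx]] = signs[k]
    return SignedNetwork(adj)


def intra_module_fraction(network: SignedNetwork, n_modules: int) -> float:
    """Fraction of edges whose endpoints share a round-robin module."""
    modules = _module_assignment(network.n_nodes, n_modules)
    edges = network.edges()
    if not edges:
        return 0.0
    same = sum(1 for s, t, _ in edges if modules[s] == modules[t])
    return same / len(edges)


# ---------------------------------------------------------------------------
# On-disk formats: edge-list TSV (source, target, sign; 1-based labels) and
# adjacency CSV with labelled header row/column.

def write_edge_list(network: SignedNetwork, path) -> None:
    rows = [
        {
            "source": network.node_labels[s],
            "target": network.node_labels[t],
            "sign": sign,
        }
        for s, t, sign in network.edges()
    ]
    pd.DataFrame(rows, columns=["source", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, node_labels: list[str] | None = None) -> SignedNetwork:
    df = pd.read_csv(path, sep="\t")
    if node_labels is None:
        node_labels = sorted(set(df["source"]) | set(df["target"]))
    index = {lab: k for k, lab in enumerate(node_labels)}
    adj = np.zeros((len(node_labels), len(node_labels)), dtype=int)
    for _, row in df.iterrows():
        adj[index[row["target"]], index[row["source"]]] = int(row["sign"])
    return SignedNetwork(adj, list(node_labels))


def write_adjacency(network: SignedNetwork, path) -> None:
    pd.DataFrame(
        network.adjacency, index=network.node_labels, columns=network.node_labels
    ).to_csv(path)


def read_adjacency(path) -> SignedNetwork:
    df = pd.read_csv(path, index_col=0)
    return SignedNetwork(df.to_numpy(dtype=int), [str(c) for c in df.columns])
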