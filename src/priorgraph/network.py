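"""Core containers: undirected networks and per-edge prior matrices.

Networks are node-labeled and undirected throughout the package; edges are
stored as lexicographically sorted node pairs so that set semantics are
unambiguous. Prior matrices hold one probability per unordered node pair,
floored at the pseudo-prior ``1e-7`` for pairs without evidence.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

#: Prior assigned to node pairs without any supporting evidence.
PSEUDO_PRIOR = 1e-7
#: Upper cap keeping priors strictly below 1 (Bernoulli sampling, prior odds).
PRIOR_CAP = 0.999999
#: Fixed prior for TF-target pairs supported by ChIP-seq binding evidence.
TF_TARGET_PRIOR = 0.99

#: Recognised per-edge prior evidence classes.
PRIOR_CLASSES = ("snp_gene", "gene_gene", "cpg_gene", "tf_target", "pseudo")


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self loop not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


class UndirectedNetwork:
    """Undirected graph over a fixed, ordered node universe.

    Parameters
    ----------
    nodes
        Node labels in a fixed total order (defines adjacency-matrix layout).
    edges
        Iterable of node pairs; order within a pair is irrelevant.
    """

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self.edges: set[tuple[str, str]] = set()
        for a, b in edges:
            self.add_edge(a, b)

    # -- basic mutation / queries ------------------------------------------------
    def add_edge(self, a: str, b: str) -> None:
        if a not in self._index or b not in self._index:
            raise KeyError(f"edge ({a!r}, {b!r}) references unknown node")
        self.edges.add(_norm_edge(a, b))

    def remove_edge(self, a: str, b: str) -> None:
        self.edges.discard(_norm_edge(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        try:
            return _norm_edge(a, b) in self.edges
        except ValueError:
            return False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def copy(self) -> "UndirectedNetwork":
        return UndirectedNetwork(self.nodes, self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UndirectedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"UndirectedNetwork({self.n_nodes} nodes, {self.n_edges} edges)"

    # -- conversions ---------------------------------------------------------------
    def to_adjacency(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = self.nodes if order is None else tuple(order)
        idx = {n: i for i, n in enumerate(order)}
        adj = np.zeros((len(order), len(order)), dtype=bool)
        for a, b in self.edges:
            if a in idx and b in idx:
                adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
        return adj

    @classmethod
    def from_adjacency(cls, adj: np.ndarray, nodes: Sequence[str]) -> "UndirectedNetwork":
        adj = np.asarray(adj)
        if adj.shape != (len(nodes), len(nodes)):
            raise ValueError("adjacency shape does not match node count")
        net = cls(nodes)
        ii, jj = np.nonzero(np.triu(adj, k=1))
        for i, j in zip(ii, jj):
            net.add_edge(nodes[i], nodes[j])
        return net

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, order: Sequence[str] | None = None) -> "UndirectedNetwork":
        nodes = tuple(order) if order is not None else tuple(sorted(g.nodes))
        return cls(nodes, ((a, b) for a, b in g.edges if a != b))


class PriorMatrix:
    """Symmetric per-edge prior probabilities over an ordered node set.

    Every unordered pair carries a value in ``[PSEUDO_PRIOR, PRIOR_CAP]`` and an
    evidence class tag; pairs never touched by evidence stay at the pseudo-prior.
    """

    def __init__(self, nodes: Sequence[str]):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        self._index = {n: i for i, n in enumerate(self.nodes)}
        p = len(self.nodes)
        self.values = np.full((p, p), PSEUDO_PRIOR)
        np.fill_diagonal(self.values, 0.0)  # diagonal unused
        self.classes = np.full((p, p), "pseudo", dtype=object)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self._index[node]

    def set_prior(self, a: str, b: str, value: float, cls: str) -> None:
        if cls not in PRIOR_CLASSES:
            raise ValueError(f"unknown prior class {cls!r}")
        i, j = self._index[a], self._index[b]
        if i == j:
            raise ValueError(f"self pair {a!r}")
        existing = self.classes[i, j]
        if existing != "pseudo" and existing != cls:
            raise ValueError(
                f"pair ({a!r}, {b!r}) already claimed by class {existing!r}, "
                f"refusing to overwrite with {cls!r}"
            )
        value = float(np.clip(value, PSEUDO_PRIOR, PRIOR_CAP))
        self.values[i, j] = self.values[j, i] = value
        self.classes[i, j] = self.classes[j, i] = cls

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def is_pseudo(self, a: str, b: str) -> bool:
        return self.get(a, b) <= PSEUDO_PRIOR

    def support(self) -> set[tuple[str, str]]:
        """Unordered pairs carrying a non-pseudo prior."""
        out = set()
        ii, jj = np.nonzero(np.triu(self.values > PSEUDO_PRIOR, k=1))
        for i, j in zip(ii, jj):
            out.add(_norm_edge(self.nodes[i], self.nodes[j]))
        return out

    def copy(self) -> "PriorMatrix":
        other = PriorMatrix(self.nodes)
        other.values = self.values.copy()
        other.classes = self.classes.copy()
        return other

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("prior matrix not symmetric")
        off = v[~np.eye(len(self.nodes), dtype=bool)]
        if off.size and (off.min() < PSEUDO_PRIOR or off.max() > PRIOR_CAP):
            raise ValueError("prior values outside [pseudo, cap]")

    @classmethod
    def constant(cls, nodes: Sequence[str], value: float) -> "PriorMatrix":
        """Uniform prior (e.g. the density prior) on every pair."""
        pm = cls(nodes)
        p = len(pm.nodes)
        v = float(np.clip(value, PSEUDO_PRIOR, PRIOR_CAP))
        pm.values = np.full((p, p), v)
        np.fill_diagonal(pm.values, 0.0)
        return pm


def pair_universe(nodes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered node pairs in lexicographic order."""
    srt = sorted(nodes)
    return [(a, b) for k, a in enumerate(srt) for b in srt[k + 1 :]]


def edge_dict_to_prior(
    nodes: Sequence[str], entries: Mapping[tuple[str, str], float], cls: str = "gene_gene"
) -> PriorMatrix:
    pm = PriorMatrix(nodes)
    for (a, b), v in entries.items():
        pm.set_prior(a, b, v, cls)
    return pm
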