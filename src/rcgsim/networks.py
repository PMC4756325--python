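"""Interaction topologies: periodic square lattice, regular random graph,
Barabási–Albert scale-free graph, and plain-text edge-list exchange.

All constructions yield simple, undirected, connected graphs stored in
compressed sparse row (CSR) form so the compiled dynamics can walk
neighbourhoods without Python overhead.  Random constructions are seeded
and regenerated (with an incremented seed) until connected, since a
disconnected component would trap imitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigurationError, EdgeListError

logger = logging.getLogger(__name__)

_MAX_CONNECTIVITY_RETRIES = 100


@dataclass(frozen=True)
class InteractionGraph:
    """Immutable adjacency structure of the population (CSR layout).

    ``indices[indptr[i]:indptr[i+1]]`` are the neighbours of vertex ``i``.
    """

    indptr: np.ndarray
    indices: np.ndarray
    name: str = field(default="graph", compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.indptr) - 1

    @property
    def n_edges(self) -> int:
        return len(self.indices) // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def edges(self):
        """Yield each undirected edge once, as (i, j) with i < j."""
        for i in range(self.n_vertices):
            for j in self.neighbors(i):
                if i < j:
                    yield i, int(j)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_edges(cls, n_vertices: int, edges, name: str = "graph") -> "InteractionGraph":
        """Build from an iterable of undirected (i, j) pairs.

        Rejects self-loops, duplicate edges, out-of-range indices, and
        disconnected results.
        """
        if n_vertices <= 0:
            raise ConfigurationError("graph must have at least one vertex")
        seen = set()
        adj: list[list[int]] = [[] for _ in range(n_vertices)]
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ConfigurationError(f"self-loop at vertex {i}")
            if not (0 <= i < n_vertices and 0 <= j < n_vertices):
                raise ConfigurationError(f"edge ({i}, {j}) out of range for N={n_vertices}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ConfigurationError(f"duplicate edge ({i}, {j})")
            seen.add(key)
            adj[i].append(j)
            adj[j].append(i)
        indptr = np.zeros(n_vertices + 1, dtype=np.int64)
        for i, nbrs in enumerate(adj):
            indptr[i + 1] = indptr[i] + len(nbrs)
        indices = np.empty(indptr[-1], dtype=np.int64)
        for i, nbrs in enumerate(adj):
            indices[indptr[i] : indptr[i + 1]] = sorted(nbrs)
        graph = cls(indptr=indptr, indices=indices, name=name)
        if not graph.is_connected():
            raise ConfigurationError("graph is not connected")
        return graph

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "graph") -> "InteractionGraph":
        mapping = {v: i for i, v in enumerate(sorted(g.nodes()))}
        return cls.from_edges(
            g.number_of_nodes(),
            ((mapping[u], mapping[v]) for u, v in g.edges()),
            name=name,
        )

    def is_connected(self) -> bool:
        """BFS reachability from vertex 0."""
        n = self.n_vertices
        if n == 1:
            return True
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        count = 1
        while stack:
            v = stack.pop()
            for w in self.neighbors(v):
                if not seen[w]:
                    seen[w] = True
                    count += 1
                    stack.append(int(w))
        return count == n


def make_square_lattice(L: int) -> InteractionGraph:
    """L x L square lattice with periodic boundaries (torus), degree 4.

    Each site interacts with its von Neumann neighbourhood.  ``L`` below 3
    is rejected: wrap-around would create multi-edges.
    """
    if L < 3:
        raise ConfigurationError(f"lattice side must be >= 3, got {L}")
    # Direct CSR construction (vectorised; correct by construction, so the
    # from_edges validation pass is skipped — it would dominate for large L).
    idx = np.arange(L * L, dtype=np.int64).reshape(L, L)
    neighbours = np.stack(
        [
            np.roll(idx, 1, axis=0),   # up
            np.roll(idx, -1, axis=0),  # down
            np.roll(idx, 1, axis=1),   # left
            np.roll(idx, -1, axis=1),  # right
        ],
        axis=-1,
    )
    indices = neighbours.reshape(-1)
    indptr = np.arange(L * L + 1, dtype=np.int64) * 4
    return InteractionGraph(indptr=indptr, indices=indices, name=f"lattice-{L}x{L}")


def make_regular_random_graph(N: int, k: int, seed: int = 0) -> InteractionGraph:
    """Random k-regular simple graph on N vertices (configuration-model style).

    Regenerated with incremented seed until connected.
    """
    if k >= N:
        raise ConfigurationError(f"degree k={k} must be < N={N}")
    if (N * k) % 2 != 0:
        raise ConfigurationError(f"N*k must be even, got N={N}, k={k}")
    if k < 1:
        raise ConfigurationError("degree must be >= 1")
    for attempt in range(_MAX_CONNECTIVITY_RETRIES):
        g = nx.random_regular_graph(k, N, seed=seed + attempt)
        if nx.is_connected(g):
            if attempt:
                logger.info("regular random graph connected after %d retries", attempt)
            return InteractionGraph.from_networkx(g, name=f"rrg-N{N}-k{k}")
    raise ConfigurationError(
        f"could not generate a connected {k}-regular graph on {N} vertices"
    )


def make_barabasi_albert(N: int, m: int, seed: int = 0) -> InteractionGraph:
    """Barabási–Albert preferential-attachment graph.

    Growth starts from a complete graph on ``m`` vertices (a single edge
    when m = 1, since a one-vertex seed has no degree to attach to); each
    new vertex attaches to ``m`` distinct existing vertices with
    probability proportional to degree.  Mean degree approaches 2m.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if N <= m:
        raise ConfigurationError(f"N={N} must exceed m={m}")
    initial = nx.complete_graph(max(m, 2))
    for attempt in range(_MAX_CONNECTIVITY_RETRIES):
        g = nx.barabasi_albert_graph(N, m, seed=seed + attempt, initial_graph=initial)
        if nx.is_connected(g):  # always true for this construction, but cheap
            if attempt:
                logger.info("BA graph connected after %d retries", attempt)
            return InteractionGraph.from_networkx(g, name=f"ba-N{N}-m{m}")
    raise ConfigurationError(f"could not generate a connected BA graph on {N} vertices")


def write_edge_list(graph: InteractionGraph, path) -> None:
    """Write one ``i j`` pair per line, 0-based, each undirected edge once."""
    with open(path, "w") as fh:
        fh.write(f"# {graph.name}: N={graph.n_vertices} E={graph.n_edges}\n")
        for i, j in graph.edges():
            fh.write(f"{i} {j}\n")


def read_edge_list(path) -> InteractionGraph:
    """Parse a plain-text edge list (whitespace-separated 0-based pairs).

    Lines starting with '#' are comments.  Malformed lines, self-loops and
    duplicate edges raise :class:`EdgeListError` with the line number.
    """
    edges = []
    seen: set[tuple[int, int]] = set()
    max_vertex = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListError(f"expected two integers, got {line!r}", lineno)
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListError(f"non-integer vertex id in {line!r}", lineno) from None
            if i < 0 or j < 0:
                raise EdgeListError(f"negative vertex id in {line!r}", lineno)
            if i == j:
                raise EdgeListError(f"self-loop at vertex {i}", lineno)
            key = (min(i, j), max(i, j))
            if key in seen:
                raise EdgeListError(f"duplicate edge ({i}, {j})", lineno)
            seen.add(key)
            edges.append((i, j))
            max_vertex = max(max_vertex, i, j)
    if not edges:
        raise EdgeListError("edge list is empty")
    try:
        return InteractionGraph.from_edges(max_vertex + 1, edges, name="edge-list")
    except ConfigurationError as exc:
        raise EdgeListError(str(exc)) from exc
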